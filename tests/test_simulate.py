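"""Synthetic-data generator: IRFs, decays, spectra, cohorts."""

import numpy as np
import pytest

from myospec import (
    CohortSpec,
    DecayModelParams,
    SimulationConfig,
    absorbance,
    band_peaks,
    convolve_irf,
    fit_decay,
    mean_lifetime,
    model_curve,
    normalize_band,
    sample_cohort_values,
    simulate_decay,
    simulate_irf,
    simulate_reflectance,
    default_cohort_spec,
    generate_cohort,
)


class TestSimulateIrf:
    def test_same_seed_reproduces_counts(self, config):
        a = simulate_irf(config, seed=5, channel=2)
        b = simulate_irf(config, seed=5, channel=2)
        c = simulate_irf(config, seed=6, channel=2)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_peak_in_first_quarter(self, config):
        irf = simulate_irf(config, seed=0)
        assert np.argmax(irf.counts) < config.n_bins // 4

    def test_near_delta_limit(self):
        cfg = SimulationConfig(
            irf_fwhm=48.8, irf_reference_lifetime=0.0, dark_offset=0.0
        )
        irf = simulate_irf(cfg, noise=False)
        order = np.argsort(irf.counts)[::-1]
        assert irf.counts[order[:3]].sum() / irf.counts.sum() >= 0.99

    def test_noiseless_shape_matches_direct_convolution(self, config):
        # oracle: explicit circular-sum convolution of the Gaussian pulse
        # with the periodic reference-dye exponential
        cfg = SimulationConfig(dark_offset=0.0)
        irf = simulate_irf(cfg, noise=False)
        n = cfg.n_bins
        t = cfg.times_ns
        T = cfg.rep_period
        sigma = cfg.irf_fwhm / 1000.0 / (2 * np.sqrt(2 * np.log(2)))
        d = (t - cfg.irf_t0 + T / 2) % T - T / 2
        g = np.exp(-0.5 * (d / sigma) ** 2)
        tau = cfg.irf_reference_lifetime / 1000.0
        e = np.exp(-t / tau) / (1 - np.exp(-T / tau))
        idx = np.arange(n)
        direct = np.array(
            [np.sum(g[(i - idx) % n] * e) for i in range(n)]
        )
        direct *= cfg.irf_total_counts / direct.sum()
        np.testing.assert_allclose(irf.counts, direct, rtol=1e-8)


class TestSimulateDecay:
    def test_noiseless_output_matches_fitter_forward_model(self, config, irf_ch4):
        # simulator (direct convolution) vs fitting module (FFT) forward
        # model; the two share no code path
        params = DecayModelParams([(0.7, 0.4), (0.3, 2.7)])
        total = 5e4
        h = simulate_decay(
            params, irf_ch4, config, noise=False, total_counts=total
        )
        pred = convolve_irf(
            model_curve(params, config.times_ns, config.rep_period), irf_ch4
        )
        pred /= pred.sum()
        n = config.n_bins
        p = config.afterpulse_prob
        signal = (total - config.dark_offset * n) / (1 + p)
        pred = signal * pred + p * signal / n + config.dark_offset
        np.testing.assert_allclose(h.counts, pred, atol=1e-10 * pred.max())

    def test_realized_totals_near_target(self, config, irf_ch4):
        params = DecayModelParams([(1.0, 2.0)])
        total = 5e4
        for i in range(100):
            h = simulate_decay(params, irf_ch4, config, seed=i, total_counts=total)
            assert abs(h.total - total) < 5 * np.sqrt(total)

    def test_round_trip_mean_lifetime_recovery(self, config, irf_ch4):
        params = DecayModelParams([(0.75, 0.41), (0.25, 2.7)])
        tm_true = mean_lifetime(params)
        tms = []
        for i in range(20):
            h = simulate_decay(params, irf_ch4, config, seed=700 + i,
                               total_counts=5e4)
            tms.append(fit_decay(h, irf_ch4, 2).tau_mean)
        assert np.mean(tms) == pytest.approx(tm_true, rel=0.05)

    def test_insufficient_budget_rejected(self, config, irf_ch4):
        params = DecayModelParams([(1.0, 2.0)])
        with pytest.raises(ValueError):
            simulate_decay(params, irf_ch4, config, total_counts=10.0)


class TestSimulateReflectance:
    def test_zero_weights_give_zero_absorbance(self, config):
        sample, ref = simulate_reflectance({}, config, noise=False)
        a = absorbance(sample, ref)
        np.testing.assert_allclose(a.values, 0.0, atol=1e-12)

    def test_oxygenated_mixture_shows_double_peak(self, config):
        sample, ref = simulate_reflectance({"oxy": 0.8}, config, noise=False)
        a = absorbance(sample, ref)
        peaks = band_peaks(a, (500.0, 600.0), min_prominence=0.05)
        centers = [w for w, _ in peaks]
        assert any(abs(c - 542.0) <= 2.0 for c in centers)
        assert any(abs(c - 577.0) <= 2.0 for c in centers)

    def test_cytochrome_mixture_peaks_at_550(self, config):
        sample, ref = simulate_reflectance(
            {"cytc": 0.7, "oxy": 0.1}, config, noise=False
        )
        a = normalize_band(absorbance(sample, ref))
        peaks = band_peaks(a, (500.0, 600.0), min_prominence=0.05)
        top = max(peaks, key=lambda p: p[1])
        assert top[0] == pytest.approx(550.0, abs=2.0)
        assert top[1] == pytest.approx(1.0, abs=1e-9)

    def test_negative_weight_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_reflectance({"oxy": -0.1}, config)


class TestCohortValues:
    def test_zero_variance_collapses_to_trajectory_mean(self):
        spec = CohortSpec(
            group_sizes={1: (2, 2)},
            trajectories={("*", "*", "tau1_ch4_ps"): (400.0, 0.0)},
            within_frac=0.3,
        )
        values, truth = sample_cohort_values(spec, seed=0, weeks=(1,))
        assert (values["value"] == 400.0).all()
        assert (truth["true_value"] == 400.0).all()
        # 9 measurements per animal/ROI
        per = values.groupby(["animal_id", "roi"]).size()
        assert (per == 9).all()

    def test_printed_mi_trajectory_endpoints(self):
        spec = default_cohort_spec()
        assert spec.lookup("MI", "LVA", "tau1_ch4_ps", 1) == (303.0, 89.0)
        assert spec.lookup("MI", "LVA", "tau1_ch4_ps", 16) == (566.0, 57.0)
        assert spec.lookup("AMC", "RV", "tau1_ch4_ps", 4) == (410.0, 60.0)
        assert spec.group_sizes == {1: (3, 3), 2: (4, 3), 4: (4, 3), 16: (6, 6)}

    def test_sampled_means_converge_to_trajectory(self):
        # n=1000 animals: empirical mean within 3 standard errors
        spec = default_cohort_spec()
        spec.group_sizes = {1: (2, 1000)}
        _, truth = sample_cohort_values(
            spec, seed=0, weeks=(1,), rois=("LVP",),
            parameters=["tau1_ch4_ps"],
        )
        mi = truth[truth["group"] == "MI"]["true_value"]
        assert abs(mi.mean() - 303.0) <= 3 * 89.0 / np.sqrt(1000)

    def test_identical_seeds_identical_cohorts(self):
        spec = default_cohort_spec()
        v1, _ = sample_cohort_values(spec, seed=9, weeks=(1,), rois=("RV",))
        v2, _ = sample_cohort_values(spec, seed=9, weeks=(1,), rois=("RV",))
        v3, _ = sample_cohort_values(spec, seed=10, weeks=(1,), rois=("RV",))
        assert v1.equals(v2)
        assert not v1["value"].equals(v3["value"])

    def test_animal_substreams_are_independent(self):
        # restricting the generated weeks must not change week-1 animals
        spec = default_cohort_spec()
        all_weeks, _ = sample_cohort_values(spec, seed=4)
        week1_only, _ = sample_cohort_values(spec, seed=4, weeks=(1,))
        merged = all_weeks[all_weeks["week"] == 1].reset_index(drop=True)
        assert merged.equals(week1_only.reset_index(drop=True))


class TestGenerateCohort:
    def test_histograms_follow_manifest_structure(self, tmp_path):
        ds = generate_cohort(seed=2, weeks=(1,), rois=("RV",), channels=(1, 4))
        assert len(ds.measurements) == (3 + 3) * 9
        m = ds.measurements[0]
        assert set(m.histograms) == {1, 4}
        assert m.histograms[4].total > 1e4
        manifest = ds.write(tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "ground_truth.csv").exists()
        assert (tmp_path / "config.json").exists()
        assert len(manifest) == len(ds.measurements)

    def test_byte_identical_for_same_seed(self, tmp_path):
        for sub in ("a", "b"):
            generate_cohort(seed=3, weeks=(1,), rois=("RV",), channels=(4,)).write(
                tmp_path / sub
            )
        f1 = sorted((tmp_path / "a").rglob("*.csv"))
        f2 = sorted((tmp_path / "b").rglob("*.csv"))
        assert [p.name for p in f1] == [p.name for p in f2]
        for p1, p2 in zip(f1, f2):
            assert p1.read_bytes() == p2.read_bytes()
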