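"""Decay model, reconvolution and fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from myospec import (
    DecayHistogram,
    DecayModelParams,
    FitOptions,
    convolve_irf,
    fit_decay,
    mean_lifetime,
    model_curve,
    periodic_decay_factor,
    reduced_chi2,
    simulate_decay,
)
from myospec.data import InstrumentResponse


def pulse_train_factor(tau, period, n_pulses=200):
    """Brute-force incomplete-decay oracle: sum the preceding pulse train."""
    k = np.arange(n_pulses)
    return np.sum(np.exp(-k * period / tau))


class TestPeriodicDecayFactor:
    @pytest.mark.parametrize(
        "tau, period, expected",
        [
            (1.0, 50.0, 1.0),  # tau << T: correction negligible
            (50.0, 50.0, 1.0 / (1.0 - np.exp(-1.0))),  # tau = T
        ],
    )
    def test_closed_form_values(self, tau, period, expected):
        assert periodic_decay_factor(tau, period) == pytest.approx(
            expected, rel=1e-9
        )

    def test_matches_pulse_train_summation(self):
        f = periodic_decay_factor(4.0, 50.0)
        assert f == pytest.approx(pulse_train_factor(4.0, 50.0), rel=1e-12)

    @pytest.mark.parametrize("bad", [(0.0, 50.0), (-1.0, 50.0), (1.0, 0.0)])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(ValueError):
            periodic_decay_factor(*bad)


class TestModelCurve:
    def test_long_lifetime_limit_is_flat(self):
        # tau >> T: the steady-state periodic decay approaches a constant;
        # residual variation over the window is ~T/tau
        t = np.arange(1024) * 0.0488
        params = DecayModelParams([(1.0, 1e8)])
        c = model_curve(params, t, 50.0)
        assert np.ptp(c) / c.mean() < 1e-6

    def test_zero_amplitude_component_is_inert(self):
        t = np.arange(256) * 0.0488
        two = model_curve(DecayModelParams([(1.0, 0.5), (0.0, 3.0)]), t, 50.0)
        one = model_curve(DecayModelParams([(1.0, 0.5)]), t, 50.0)
        np.testing.assert_allclose(two, one)

    def test_linearity_in_components(self):
        t = np.arange(256) * 0.0488
        both = model_curve(
            DecayModelParams([(1.0, 0.5), (0.5, 3.0)]), t, 50.0
        )
        parts = model_curve(DecayModelParams([(1.0, 0.5)]), t, 50.0) + model_curve(
            DecayModelParams([(0.5, 3.0)]), t, 50.0
        )
        np.testing.assert_array_equal(both, parts)

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            DecayModelParams([])


def _delta_irf(n=256, at=0):
    counts = np.zeros(n)
    counts[at] = 10000.0
    return InstrumentResponse(
        counts=counts, bin_width=48.8, rep_period=50.0, reference_lifetime=0.0
    )


class TestConvolveIrf:
    def test_delta_kernel_is_identity(self, rng):
        curve = rng.random(256)
        out = convolve_irf(curve, _delta_irf(), irf_shift=0.0)
        np.testing.assert_allclose(out, curve, atol=1e-12 * curve.max())

    def test_unit_area_kernel_conserves_counts(self, config, irf_ch4, rng):
        curve = rng.random(config.n_bins) * 100
        out = convolve_irf(curve, irf_ch4)
        assert out.sum() == pytest.approx(curve.sum(), rel=1e-9)

    def test_matches_direct_summation(self, rng):
        # O(N^2) circular convolution oracle vs the FFT implementation
        n = 1024
        curve = rng.random(n)
        t = np.arange(n)
        g = np.exp(-0.5 * ((t - 100) / 6.0) ** 2)
        irf = InstrumentResponse(
            counts=1e4 * g, bin_width=48.8, rep_period=50.0
        )
        kernel = irf.kernel()
        direct = np.array(
            [np.sum(kernel * curve[(i - t) % n]) for i in range(n)]
        )
        out = convolve_irf(curve, irf)
        np.testing.assert_allclose(out, direct, atol=1e-8 * direct.max())

    def test_grid_mismatch_rejected(self, irf_ch4):
        with pytest.raises(ValueError):
            convolve_irf(np.ones(100), irf_ch4)


class TestMeanLifetime:
    def test_single_component_returns_tau(self):
        assert mean_lifetime(DecayModelParams([(3.0, 2.5)])) == 2.5
        assert mean_lifetime(DecayModelParams([(1.0, 1.0), (0.0, 9.0)])) == 1.0

    def test_hand_computed_value(self):
        # equal amplitudes, tau 1 and 3 ns: (1 + 9) / (1 + 3)
        params = DecayModelParams([(1.0, 1.0), (1.0, 3.0)])
        assert mean_lifetime(params) == pytest.approx(2.5)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            mean_lifetime(DecayModelParams([(0.0, 1.0), (0.0, 2.0)]))

    @given(
        a1=st.floats(0.01, 100),
        a2=st.floats(0.01, 100),
        t1=st.floats(0.01, 20),
        t2=st.floats(0.01, 20),
    )
    def test_bounded_by_component_lifetimes(self, a1, a2, t1, t2):
        params = DecayModelParams([(a1, t1), (a2, t2)])
        tm = mean_lifetime(params)
        assert min(t1, t2) - 1e-12 <= tm <= max(t1, t2) + 1e-12
        amp_weighted = (a1 * t1 + a2 * t2) / (a1 + a2)
        assert tm >= amp_weighted - 1e-9 * max(t1, t2)

    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_to_amplitude_scaling(self, scale):
        base = DecayModelParams([(1.0, 0.4), (0.5, 2.7)])
        scaled = DecayModelParams([(scale, 0.4), (0.5 * scale, 2.7)])
        assert mean_lifetime(scaled) == pytest.approx(mean_lifetime(base), rel=1e-9)


class TestReducedChi2:
    def test_exact_fit_gives_zero(self):
        obs = np.array([5.0, 7.0, 9.0])
        assert reduced_chi2(obs, obs, 0) == 0.0

    def test_hand_computed(self):
        assert reduced_chi2([4.0, 9.0], [2.0, 12.0], 0) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reduced_chi2([1.0, 2.0], [1.0], 0)

    def test_correct_model_gives_unit_chi2(self, config, irf_ch4):
        # Poisson realisations of a known decay, refitted: median chi2_r ~ 1
        true = DecayModelParams([(0.6, 0.5), (0.4, 3.0)])
        chis = []
        for i in range(50):
            h = simulate_decay(
                true, irf_ch4, config, seed=3000 + i, total_counts=5e4
            )
            fr = fit_decay(h, irf_ch4, 2)
            chis.append(fr.chi2_reduced)
        assert 0.8 <= np.median(chis) <= 1.2


class TestFitDecay:
    def test_noiseless_single_exponential_self_consistency(self, config, irf_ch1):
        true = DecayModelParams([(1.0, 2.0)])
        h = simulate_decay(
            true, irf_ch1, config, noise=False, total_counts=1e6, channel=1
        )
        fr = fit_decay(h, irf_ch1, 1)
        assert fr.converged
        assert fr.params.components[0][1] == pytest.approx(2.0, rel=1e-3)

    def test_components_sorted_ascending(self, config, irf_ch4):
        true = DecayModelParams([(0.25, 2.7), (0.75, 0.4)])
        h = simulate_decay(true, irf_ch4, config, seed=7, total_counts=5e4)
        fr = fit_decay(h, irf_ch4, 2)
        taus = fr.params.taus
        assert taus[0] < taus[1]
        assert fr.intensity_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert taus[0] <= fr.tau_mean <= taus[1]

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_overparameterized_fit_degrades_gracefully(self, config, irf_ch4, seed):
        # double-exponential model on single-exponential truth: the two
        # fitted components must cluster around the true lifetime rather
        # than invent a well-separated spurious component.  The
        # intensity-weighted dispersion of the fitted pair stays small and
        # the mean lifetime stays on the truth.
        true = DecayModelParams([(1.0, 1.5)])
        h = simulate_decay(true, irf_ch4, config, seed=seed, total_counts=1e5)
        fr = fit_decay(h, irf_ch4, 2)
        f = fr.intensity_fractions
        taus = fr.params.taus
        dispersion = np.sqrt(np.sum(f * (taus - fr.tau_mean) ** 2)) / fr.tau_mean
        assert dispersion < 0.15
        assert fr.tau_mean == pytest.approx(1.5, rel=0.05)

    def test_insufficient_counts_rejected(self, config, irf_ch1):
        h = DecayHistogram(
            counts=np.ones(1024), bin_width=48.8, rep_period=50.0, channel=1
        )
        with pytest.raises(ValueError, match="insufficient"):
            fit_decay(h, irf_ch1, 1, FitOptions(min_counts=1e5))

    def test_all_zero_histogram_rejected(self, irf_ch1):
        h = DecayHistogram(
            counts=np.zeros(1024), bin_width=48.8, rep_period=50.0, channel=1
        )
        with pytest.raises(ValueError):
            fit_decay(h, irf_ch1, 1)

    def test_double_exponential_parameter_recovery(self, config, irf_ch4):
        # well-separated lifetimes, both fractions >= 15%, 5e4 counts:
        # lifetimes within 10%, mean lifetime within 5% (mean over 20 seeds)
        true = DecayModelParams([(0.75, 0.5), (0.25, 3.0)])
        tm_true = mean_lifetime(true)
        t1s, t2s, tms = [], [], []
        for i in range(20):
            h = simulate_decay(
                true, irf_ch4, config, seed=500 + i, total_counts=5e4
            )
            fr = fit_decay(h, irf_ch4, 2)
            assert fr.converged
            t1s.append(fr.params.taus[0])
            t2s.append(fr.params.taus[1])
            tms.append(fr.tau_mean)
        assert np.mean(t1s) == pytest.approx(0.5, rel=0.10)
        assert np.mean(t2s) == pytest.approx(3.0, rel=0.10)
        assert np.mean(tms) == pytest.approx(tm_true, rel=0.05)
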