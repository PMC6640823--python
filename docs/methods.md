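# Methods

## Decay model and reconvolution fitting

The fluorescence signal in each detection channel is modelled as a sum of
1–2 exponential components with amplitudes αᵢ and lifetimes τᵢ plus a
constant offset C.  Three instrument effects are built into the forward
model:

- **Incomplete decay.**  At a 20 MHz repetition rate the 50 ns period is
  comparable to the longer lifetimes, so emission excited by preceding
  pulses piles into the current period.  Under steady-state periodic
  excitation each component's observed decay is the geometric sum
  Σ_{k≥0} e^{−(t+kT)/τ} = e^{−t/τ}/(1 − e^{−T/τ}); we apply the closed-form
  factor 1/(1 − e^{−T/τ}) per component and perform the IRF convolution
  *circularly* over one period, which is exactly the steady-state response
  of a periodic system.  The closed form agrees with a brute-force
  200-pulse summation to better than 1e−10 relative over τ/T ∈ [0.01, 2]
  (tested).

- **IRF reconvolution.**  The IRF is the measured reference-dye histogram
  (nominal dye lifetime ~200 ps), background-subtracted using the mean of
  the first 5% of bins (pre-rise) and normalized to unit area.  A sub-bin
  timing shift between the dye and tissue measurements is unavoidable, so
  the shift is a free fit parameter bounded to ±3 bins, implemented as
  linear interpolation between integer circular shifts.  An optional
  correction that deconvolves the nominal dye lifetime from the measured
  IRF is provided but off by default: the dye histogram is treated directly
  as the IRF, and the simulator generates data the same way, so default
  analyses are internally consistent.

- **Afterpulsing.**  PMT afterpulses are approximated as a time-uniform
  background proportional to the detected signal, level p·S/N counts per
  bin with p = 0.01 by default (configurable per channel, optionally
  fitted).  C remains a separate free dark/ambient offset.

### Weighting

Fits minimise weighted least squares on the histogram.  The default
weights are **model-based (Pearson)**: residual = (model − counts) /
√max(model, 0.25).  At this instrument's photon budgets the per-bin counts
are low (channel 1 collects ~5×10³ photons over 1024 bins, i.e. a few
counts per bin), and data-based Neyman weights 1/max(counts, 1)
systematically over-weight downward fluctuations, biasing fitted lifetimes
low by 6–9% in our simulations; model-based weights reduce the bias to
1–2%, which is what the recovery tests require.  Neyman weighting remains
available (`FitOptions.weighting="neyman"`).  The 0.25-count variance
floor only matters in near-empty bins; bias is insensitive to floors
≤ 0.5.  The reported goodness-of-fit diagnostic is the conventional
Neyman reduced χ² = Σ(obs−fit)²/max(obs,1)/(N − n_free) regardless of the
fitting weights.

### Optimisation

`scipy.optimize.least_squares` (trust-region reflective) over
[α₁..α_n, τ₁..τ_n, C, shift].  Bounds: τ ∈ [0.01, 20] ns, α ≥ 0,
C ∈ [0, max count], shift ±3 bins.  Initial lifetimes come from the
log-slope of the decay tail between its 80% and 20% levels; a double
exponential starts at (τ₀/4, 2τ₀) with the amplitude total matched to the
observed signal.  Up to three deterministic multiplicative perturbations
of the starting lifetimes are tried when the optimiser fails or leaves a
reduced χ² above 2; the best attempt is kept and flagged `converged=False`
if unsuccessful — never silently dropped.  Components are sorted by τ
ascending after fitting, so τ₁ always denotes the short component.
Channel policy: single exponential for channel 1, double for channels 2–4;
channel 3 mixes collagen, NAD(P)H and FAD fluorescence and is therefore
fitted but excluded from default reports.

## Intensity fractions and absorbance

Fₙ = Iₙ/(I₁+I₂+I₃) with channel 4 excluded (separate excitation laser and
coupling path).  Iₙ is the histogram total minus the fitted offset C×N
when a fit exists, else the raw total.  Absorbance is
A(λ) = −log₁₀(I/I₀) against the daily white-reference spectrum; the
reference is linearly interpolated onto the sample grid when needed, and
non-positive sample bins become NaN rather than fabricated values.
Normalization of absorbance spectra divides by the maximum inside the
500–600 nm band (the convention that makes spectra peak at 1 in that
band); it is idempotent and gain-invariant.  Peak finding uses 3-point
local maxima with a prominence threshold relative to the in-band range.

## Cohort statistics

The unit of analysis is the animal: the 3 positions × 3 repeats per region
are averaged first, avoiding pseudo-replication.  Welch's unequal-variance
t-test (two-sided; Welch–Satterthwaite df), step-down Holm–Šídák
adjustment p_adj(i) = 1 − (1 − p_(i))^(m−i+1) with monotonicity
enforcement, and Cohen's d with pooled SD.  The default adjustment family
is the set of week-wise comparisons of one parameter within one region
(m = 4), configurable to one global family or none.  Signs follow
MI − control.  Simulated null cohorts at the study's group sizes give a
familywise type-I error within the nominal 0.05 (+ Monte-Carlo slack)
(tested at 1000 replicates).

## Synthetic-data generator

The generator emulates the study's measurement structure so the entire
pipeline is exercised end to end:

- **Instrument:** 1024 bins × 48.8 ps ≈ 50 ns window at 20 MHz; Gaussian
  IRF of 300 ps FWHM convolved with the 200 ps reference-dye decay, peak
  at 5 ns; photon budgets 5×10³ (channel 1) and 5×10⁴ (channels 2–4);
  afterpulse probability 0.01; dark offset 0.2 counts/bin.  All counts are
  Poisson-sampled; a noiseless mode returns the expected curve.
- **Design:** groups control (AMC) 3/4/4/6 and MI 3/3/3/6 animals at weeks
  1/2/4/16; regions RV, LVP (remote viable), LVA (infarct); 3 positions ×
  3 repeats per region.
- **Ground truths:** per animal, each parameter is drawn from
  Normal(trajectory mean, between-animal SD), truncated at 10% of the mean
  to stay physical; each measurement perturbs the animal value with a
  within-measurement SD set to 30% of the between-animal SD (the
  within-region spatial variability is not separately known; this split is
  a modelling choice).  The headline trajectory is the channel-4 short
  lifetime: MI 303 ± 89 ps (week 1) → 566 ± 57 ps (week 16) with weeks 2
  and 4 interpolated linearly in log₂(week) (369 ± 81, 434 ± 73 ps),
  control constant 410 ± 60 ps.  The channel-1 lifetime in the MI infarct
  rises 1.8 → 2.6 → 3.3 → 4.2 ns.  Remaining decay parameters, channel
  fractions and chromophore weights are stylised constants chosen to
  reproduce the qualitative phenomenology (MI blue shift; growing reduced
  cytochrome c contribution in remote regions; oxygenated-blood signature
  in the infarct).
- **Reflectance:** chromophore absorbances are stylised Gaussian bands
  (oxy 542/577 nm, reduced cytochrome c 520/550 nm, deoxy 555 nm), not
  literature extinction curves; the sample spectrum is the smooth lamp
  reference attenuated by 10^(−A) with 1% multiplicative noise.
- **Randomness:** one `SeedSequence` per cohort with disjoint spawn keys
  per animal, measurement and channel — identical seeds give byte-identical
  datasets and changing one animal's draw never perturbs another's.  The
  simulator's forward model (direct time-domain circular convolution) is
  implemented independently of the fitting module's FFT reconvolution, and
  the two agree to 1e−10, cross-validating both.

What passing tests therefore show: the fitting chain recovers the decay
parameters the generator encodes, at the study's photon budgets and group
sizes, under Poisson noise and the modelled instrument effects.  What they
do not show: robustness to effects the generator omits — tissue-optics
distortions (scattering, probing depth, blood-pool absorption), motion,
detector nonlinearity or dead time, day-to-day IRF drift beyond a timing
shift, or non-exponential decay physics.

## Problem sizes

Default analyses use 1024-bin histograms; recovery statistics average 20
Poisson replicates per condition; null calibration uses 1000 simulated
cohorts; the end-to-end demonstration fits the full 32-animal default
cohort on channel 4.  These sizes make the whole suite run in a couple of
minutes on a laptop core while keeping Monte-Carlo error well inside the
tolerances tested.

## Known limitations

- No phasor analysis, global multi-curve fitting, or maximum-likelihood
  variant; no vendor binary file parsing.
- The afterpulsing and incomplete-decay formulations are stated model
  assumptions (uniform background; geometric pile-up), not calibrated
  detector physics.
- Absorbance spectra are interpreted qualitatively (band normalization and
  peak positions); no quantitative chromophore unmixing.
- The multiple-comparison family is a configuration choice; different
  family definitions change adjusted p-values.
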