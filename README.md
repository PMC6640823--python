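# myospec

Label-free optical spectroscopy analysis of myocardium: time-correlated
single photon counting (TCSPC) autofluorescence decay fitting, spectral
intensity fractions, diffuse-reflectance absorbance, and cohort statistics —
with a synthetic-data generator that emulates the full in vivo measurement
design, so every stage runs and is testable without any instrument data.

## The problem

After myocardial infarction (MI) the heart remodels: collagen is deposited
in and around the infarct scar while the remaining viable myocardium shifts
its energetic state.  Both processes leave label-free optical signatures.
Collagen's long fluorescence lifetime raises the autofluorescence lifetime
in the infarct; changes in the FAD-dominated emission band (channel 4,
525 ± 25 nm at 438 nm excitation) track metabolism — in particular the
short decay component τ₁ of channel 4, which falls acutely after MI and
then rises with collagen (≈300 ps at week 1 to ≈570 ps at week 16 in MI
animals, ≈410 ps in age-matched controls).  Diffuse reflectance adds the
haemoglobin/myoglobin oxygenation double peak (~542/577 nm) and the reduced
cytochrome c peak (~550 nm).

This package is for experimenters building or analysing single-point
fibre-optic autofluorescence-lifetime + reflectance instruments who need a
tested, reusable implementation of the analysis chain.

## The model

A measured decay histogram is fitted with a multi-exponential model under
periodic excitation at repetition period T (50 ns at 20 MHz),

```
I(t) = Σᵢ αᵢ e^(−t/τᵢ) / (1 − e^(−T/τᵢ))   ⊛  IRF(t − Δ)   +  p·S/N  +  C
```

where the geometric factor handles incomplete decay (pile-up of preceding
pulses), ⊛ is circular convolution with the measured instrument response
function (IRF, reference-dye histogram), Δ a fitted sub-bin timing shift,
p·S/N a time-uniform afterpulsing background proportional to the detected
signal S, and C a constant offset.  Fits minimise model-weighted (Pearson)
Poisson least squares; channel 1 uses a single exponential (low photon
counts), channels 2–4 double exponentials.  The intensity-weighted mean
lifetime is

```
τ_mean = (α₁τ₁² + α₂τ₂²) / (α₁τ₁ + α₂τ₂)
```

Channel fractions are Fₙ = Iₙ/(I₁+I₂+I₃); tissue absorbance is
A(λ) = −log₁₀(I(λ)/I₀(λ)) against a daily white-reference spectrum.
Group comparisons (control vs MI per week, region and parameter) use
Welch's t-test on per-animal means (9 measurements averaged per region),
step-down Holm–Šídák adjustment, Cohen's d, and the usual star notation.

## Worked example

Simulate one channel-4 histogram at the week-1 MI ground truth and fit it:

```python
from myospec import *

config = SimulationConfig()                      # 1024 bins x 48.8 ps, 20 MHz
irf = simulate_irf(config, seed=0, channel=4)    # ~200 ps reference-dye IRF

# MI week-1 ground truth: tau1 = 303 ps, tau2 = 2.7 ns, 75% short amplitude
truth = DecayModelParams([(0.75, 0.303), (0.25, 2.7)])
hist = simulate_decay(truth, irf, config, seed=1, total_counts=5e4)

fit = fit_decay(hist, irf, n_components=2)
tau1, tau2 = fit.params.taus
print(f"tau1 = {tau1*1000:.0f} ps   tau2 = {tau2:.2f} ns")
print(f"tau_mean = {fit.tau_mean:.2f} ns   chi2_r = {fit.chi2_reduced:.2f}")
```

prints

```
tau1 = 322 ps   tau2 = 2.77 ns
tau_mean = 2.12 ns   chi2_r = 0.98
```

A single 50 000-photon histogram recovers the 303 ps short component to
within its shot-noise scatter (322 ps here; the mean over 20 realisations
lands within a few percent of truth) with a reduced χ² near 1.  The full
cohort pipeline runs from the command line:

```
myospec run-all --out results/ --seed 42
```

which simulates the default cohort (control 3/4/4/6 and MI 3/3/3/6 animals
at weeks 1/2/4/16, three regions, 3 positions × 3 repeats), fits every
histogram, computes channel fractions and normalized absorbance spectra,
and writes `fits.csv`, `animals.csv`, `comparisons.csv` and
`spectra_normalized.csv`.  Reruns with the same seed are byte-identical.

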