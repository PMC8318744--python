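# Methods

## Measurement model

The package assumes Beer–Lambert additivity on a shared wavelength grid:
the absorbance of an n-component mixture at wavelength λ is
`A(λ) = Σᵢ hᵢ(λ)·cᵢ + ε(λ)`, with absorptivities `hᵢ` in AU·mL/µg,
concentrations `cᵢ` in µg/mL, and `ε` zero-mean instrument noise. The
model is linear and static: no baseline drift, no analyte interaction, no
wavelength jitter. Calibration is single-point — each component's column
of the sensitivity matrix is one standard spectrum divided by its known
concentration — so any error in a standard propagates proportionally into
every estimate; this matches assay practice where one mid-range standard
per component is scanned alongside the samples.

## The sequential filter

The concentration vector is treated as a static state observed through
one scalar measurement per wavelength. Each step applies the standard
Kalman update (innovation `e = A − h·ĉ`, gain `g = P·h/(h·P·h + r)`,
`ĉ ← ĉ + g·e`, `P ← P − g·(h·P)`), sweeping the grid in ascending
wavelength order and repeating full sweeps — carrying ĉ and P forward —
until the largest component-wise change over a sweep falls below a
tolerance. Because the state is static and the data are re-used, k sweeps
are equivalent to ridge-regularized least squares with ridge
`r/(k·P₀)`; with the default diffuse prior this bias is ~10⁻¹² relative
after one sweep, so the converged filter coincides with the batch CLS
solution. That equivalence is the package's primary correctness check:
`cls_oracle` solves the normal equations `(HᵀH)ĉ = HᵀA` independently,
and a property test requires agreement within 1e-6 relative on hundreds
of random full-rank systems.

Defaults and their reasons:

| parameter | default | unit | why |
|---|---|---|---|
| `prior_mean` | 0 | µg/mL | no information before the scan |
| `prior_variance` | 10⁶ | (µg/mL)² | diffuse: converged estimate ≡ CLS far below reporting precision |
| `measurement_variance` r | 10⁻⁶ | AU² | order of a typical photometric noise floor (0.001 AU SD); affects only gain schedule and reported covariance, not the converged estimate |
| `passes` | 50 | — | safety cap; convergence typically occurs at pass 2–3 |
| `tolerance` | 10⁻⁹ | µg/mL | far below any chemical meaning; makes order-invariance and oracle tests sharp |

Numerical choices: the plain covariance update is default (81 steps ×
2–4 components is benign); a Joseph-form update is available behind a
flag for ill-conditioned cases. Covariance symmetry is re-enforced after
every step, and positive semi-definiteness is checked after each sweep
(eigenvalue floor −10⁻¹⁰·P₀), raising a stability error that suggests a
larger r rather than returning garbage. Negative concentration estimates
are reported with a warning, never clipped — clipping would bias recovery
and repeatability statistics. Heteroscedastic noise is supported by
passing a per-wavelength r vector; the scalar default reflects that no
wavelength-dependent noise model is assumed.

`innovation_diagnostics` summarizes the innovation sequence (mean,
variance, lag-1 autocorrelation, the latter defined as the Pearson
correlation of the sequence with its one-step shift, NaN for constant
sequences). Near-zero mean and autocorrelation indicate the linear model
explains the spectrum; structure indicates a missing absorber.

## Validation calculus

All statistics use the sample (n−1) standard deviation, and computation
is kept at full precision — rounding half-up to a table's printed
precision happens only in the report renderer. This ordering matters:
several published repeatability values can only be reproduced from
unrounded inputs.

* RE% = (C − C₀)·100/C₀, signed.
* RSD% = SD·100/mean, judged against half the Horwitz value
  `RSD_H = 2^(1 − 0.5·log₁₀C)` with C a mass fraction
  (5 µg/mL → 5×10⁻⁶). The bound is strictly decreasing in C.
* LOD = 3.3·SD, LOQ = 10·SD from ≥ 7 replicate quantifications of a
  solution near the expected detection limit (fewer replicates warn,
  below 2 is an error).
* Recovery Rev% = (C₂ − C₁)·100/Cs, pairing replicate k of each spiked
  level with replicate k of the unspiked set; the report flags values
  outside 85–110%.
* Tablet content = `d·Cᵢ·M/m` mg/tablet, with d the collapsed dilution
  factor (default 2.5 for the dissolve-250-mL / dilute-10-to-100 chain),
  M the average tablet weight and m the powder weight taken.
* Two-method comparison: F = larger/smaller sample variance, compared to
  the upper α/2 F-quantile (the two-sided convention analytical F-tables
  use — F(0.05; 2; 2) = 39.00); pooled-SD t-test, two-sided at
  n₁+n₂−2 degrees of freedom. Swapping the two methods leaves every
  statistic unchanged.

## Synthetic spectra

Each component is a sum of Gaussian bands (center, σ, peak absorptivity);
mixtures are exact Beer–Lambert sums plus i.i.d. Gaussian absorbance
noise. The presets emulate the HCT/LSP tablet system on the 220–300 nm,
1 nm grid: an HCT-like component with bands at 272 nm (σ 9 nm,
0.070 AU·mL/µg) and 225 nm (σ 6, 0.050), and an LSP-like component with
a dominant band at 235 nm (σ 10, 0.030) plus a weak shoulder at 270 nm
(σ 14, 0.0045). These constants are fixture plumbing, not measured
absorptivities; they were chosen so the 5 and 20 µg/mL standards peak at
0.35 and 0.60 AU (a plausible photometric range) and the two unit
spectra have cosine similarity ≈ 0.47 — genuinely overlapping, the
regime the filter exists for.

The default noise SD of 0.002 AU is a tuning constant representing a
typical bench spectrophotometer; with it the Monte-Carlo study lands in
the sub-percent RE/RSD range a real assay of this kind reports. The
generator seeds one `SeedSequence` and gives every file and replicate
its own child stream, so a whole study regenerates byte-identically from
one seed while replicates stay independent.

What the generator does **not** emulate: baseline drift, stray light,
wavelength jitter, excipient/matrix absorption, heteroscedastic or
correlated noise, and calibration-standard preparation error. Passing
the synthetic studies therefore demonstrates the estimator and the
statistics pipeline are correct under the model's own assumptions; it
does not certify performance on real tablets, where matrix effects and
baseline artifacts dominate the error budget.

## Study harnesses and problem sizes

`pipeline.accuracy_study` quantifies 100 noisy replicates of each of the
seven designed mixtures (HCT:LSP ratios 1:24 … 6:4 plus the nominal 5:20)
against a noiseless preset calibration, reporting mean |RE%|, RSD% and
the half-Horwitz bound per design and component. Calibration is kept
noiseless here deliberately: the study isolates what measurement noise on
the sample spectrum does to the estimates, the quantity the repeatability
criterion addresses. The end-to-end fixture (`generate_study_fixture`,
CLI `simulate`) instead puts noise on every spectrum including standards,
which is the realistic pipeline test and carries a correspondingly looser
expectation (a few percent).

`pipeline.lod_study` quantifies 7 replicates of a low-level solution
(defaults 0.10 µg/mL HCT-like, 0.50 µg/mL LSP-like — a few multiples of
the noise-propagated estimate SD, i.e. "near the expected detection
limit"; the composition is this package's choice). Its closed-form oracle
is the CLS covariance: the estimate SD is σ·√((HᵀH)⁻¹ᵢᵢ), giving
predicted LODs of ≈ 0.023 (HCT-like) and 0.057 (LSP-like) µg/mL at
σ = 0.002 AU; a seeded run is required to land within a factor of two of
this prediction (the sampling band of a 7-replicate SD).

The oracle-equivalence check uses 200 random systems of 2–4 components
on 10–81 wavelengths with uniform(0.01, 1) absorptivities — full rank
with overwhelming probability and verified per draw.

## Known limitations

* Single-point calibration: no linearity check across a concentration
  range is performed (none is possible with one standard per component).
* The filter is linear and static; drifting baselines or saturating
  absorbances need state augmentation or weighting that is out of scope.
* The bundled example measurements are printed results of a published
  tablet assay, included to exercise the arithmetic; their raw spectra
  are not available, so spectrum-level reproduction of those tables is
  not possible and is not claimed.
* Innovation diagnostics are descriptive; no formal whiteness test is
  attached.
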