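# Methods

`ftirmacro` re-implements, as a tested library, the spectral-analysis
workflow used to profile macromolecular changes in cultured epithelial
cells by ATR-FTIR — in particular the dose-response design in which cells
are exposed to low concentrations of a solvent (DMSO, 0.1–1.5% v/v) and
compared to untreated controls. Because no public spectra exist for this
kind of study, the package ships a first-class synthetic-spectrum
generator that emulates the experiment; every analysis stage is tested
against it.

## Synthetic spectra

A sample spectrum on the default grid (4000→650 cm⁻¹, 1 cm⁻¹ spacing,
emulating a 4 cm⁻¹-resolution instrument's interpolated export) is

    A(ν) = Σ_b a_b · g_b(ν) + baseline(ν) + w · g_water(ν) + ε(ν)

where each `g_b` is a unit-height band profile (gaussian by default;
Lorentzian and pseudo-Voigt available because condensed-phase bands have
Lorentzian character), the baseline is a non-negative offset + tilt +
broad hump, the residual free-water band sits at 2125 cm⁻¹ (fwhm 70), and
ε is i.i.d. gaussian noise. The band inventory covers the amide A/I/II
envelope, CH₂/CH₃ and olefinic stretches, the phosphate antisymmetric
sub-bands assigned to A-form (1240 cm⁻¹) and B-form (1221 cm⁻¹) DNA, the
Z-DNA marker at 1066 cm⁻¹, the cholesteryl-ester band at 1172 cm⁻¹, a
carbohydrate/backbone band at 1025 cm⁻¹ and the ribose ring band at
915 cm⁻¹. Amplitudes are in absorbance units on the scale of a dried
5×10⁵-cell film (amide I ≈ 0.08–0.1 total).

Two geometric choices are deliberate and matter downstream:

* **Amide-I sub-band width 8.5 cm⁻¹.** The four secondary-structure
  components (α 1657/1649, β 1636/1629 cm⁻¹) are effective
  second-derivative sub-bands. At widths ≥ 9 cm⁻¹ the 1636 component's
  second-derivative wings bleed into the 1649 search window and bias the
  recovered α→β conversion upward by 1–2 percentage points; at 8.5 cm⁻¹
  the estimator is near-unbiased.
* **No separate phosphate symmetric band near 1080 cm⁻¹.** A band there
  would overlap the 1071–1061 cm⁻¹ Z-DNA search window in
  second-derivative space and make exact multiplier recovery impossible;
  that intensity is subsumed into the 1025 cm⁻¹ band. (The matching
  optional band *assignment* at 1080 cm⁻¹ exists in the quantification
  table but is disabled by default.)

**Dose effects.** An `EffectModel` maps dose to per-band amplitude
multipliers, plus a compositional α→β conversion: fraction *c* of each
α-component amplitude is removed and the removed total is split equally
over the two β components, so summed amide-I amplitude is conserved (the
paper-style conversion figures of 15/30/40% at 0.1/0.5/1.5% v/v are the
default *c* values; the 50/50 β split is a choice — only totals are ever
reported for such data). Doses absent from the tables are linearly
interpolated (1.0% is deliberately absent by default). Multiplier
magnitudes for bands whose change is known only qualitatively
(nucleic-acid decrease, Z enhancement, ester decrease, cell-line-specific
olefinic response) are **emulation parameters, not measured values**;
they were calibrated so that, at n = 9 technical replicates and default
noise, the t-test tier pattern reproduces the qualitative result layout
(Z marker significant at every dose, ribose at every dose, phosphate
envelope only at the top doses, ester from mid-dose). Three cell-line
profiles are bundled (`HCT116_like`, `SW480_like`, `MCF10A_like`),
differing mainly in lipid-band amplitudes and in the sign/placement of
the olefinic dose response.

**Replicate structure and noise.** One log-normal amplitude jitter per
band per biological replicate (σ_log = 0.02), shared by that replicate's
technical replicates and doses; per-sample log-normal scatter of baseline
(σ = 0.10) and water-band (σ = 0.05) scale; detector noise σ = 2×10⁻⁴
absorbance — the order of a 64-scan ATR average. The paper-free choices
here (jitter and noise magnitudes, absolute band amplitudes) were made
once as realistic values; they set the difficulty of every recovery test.
All randomness flows from a single seed; identical seeds give
bit-identical spectrum sets.

**What the generator does not emulate:** interferograms, ATR
penetration-depth dispersion, Mie scattering, atmospheric CO₂/H₂O vapor
lines, detector drift, or non-gaussian noise. Passing recovery tests
therefore show that the *analysis chain* is correct and well calibrated
under the stated statistical model — not that it is robust to every
artefact of real instruments.

## Preprocessing

* **Background subtraction with water flattening.** The PBS reference is
  subtracted as `sample − k·reference`, with `k` chosen by least squares
  so the difference is maximally straight inside 2200–2050 cm⁻¹ (the
  window bracketing the residual free-water band). The original
  procedure is manual in vendor software; the straight-line objective is
  this package's formalization. `k` is recorded per sample.
* **Savitzky–Golay second derivative**, window 9 points, polynomial
  order 3 (a common vendor-style setting for 4 cm⁻¹ data on a 1 cm⁻¹
  grid; both configurable), edge points from the truncated-window
  polynomial fit. Derivatives are taken with respect to wavenumber.
* **Vector normalization** (division by the Euclidean norm, optionally
  over a region) follows the derivative — "second derivative and
  vector-normalized" order — because derivative traces contain positive
  and negative values. Min/max normalization (global min → 0, max within
  an anchor window, typically amide I/II, → 1) is provided for
  qualitative use.
* **Regions** are closed wavenumber intervals, endpoints included when
  on-grid. Defaults: whole 4000–650, lipid 3030–2830, nucleic acid
  1250–1200 cm⁻¹. (Sources for this kind of study quote the lipid region
  both as 3030–2800 and 3030–2830 cm⁻¹; the default is 3030–2830 and the
  bound is configurable.)

## Band quantification

Absorbance-sourced bands (the phosphate antisymmetric envelope at
1242–1238 cm⁻¹ and, optionally, the symmetric band) are read as the
window maximum of the vector-normalized absorbance spectrum; all other
markers are read from the vector-normalized second derivative as the
magnitude of the window minimum (absorbance maxima are second-derivative
minima). Search windows default to center ± 4 cm⁻¹ (the instrument
resolution) except the Z-DNA band (1071–1061 cm⁻¹, a published figure
window) and the phosphate envelope (1242–1238 cm⁻¹). Extremum ties break
toward the literature center.

Derived statistics:

* **Percent of untreated:** `100 · I / mean(I_untreated)` per band
  within each cell line; the untreated group mean is exactly 100.
* **Z-DNA enhancement:** per sample `r = I(1066)/(I(1240)+I(1221))`,
  reported per dose as fold change of the group mean ratio versus
  untreated. Being a within-spectrum ratio it is exactly invariant to
  normalization, which is why noise-free multiplier recovery is exact
  (≤ 10⁻⁶ relative). Note the fold conflates Z-band enhancement with any
  change in the A+B denominator — at the default model the 1.5% fold is
  ≈ 2.1 because the multiplier 1.7 is divided by the 0.8 nucleic-acid
  decrease. That is a property of the statistic, faithfully reproduced.
* **Lipid unsaturation:** total lipid = sum of the percent intensities
  of olefinic (3009), CH₂ antisym (2921), CH₂ sym (2852) and cholesteryl
  ester (1172 cm⁻¹); the unsaturation index is 100·olefinic/total.
* **Secondary-structure conversion:** α = I(1657)+I(1649),
  β = I(1636)+I(1629); conversion(dose) = 100·(1 − mean α(dose)/mean
  α(UT)). No formula exists in the source literature for "conversion";
  relative α loss is this package's definition, and the β gain is
  reported separately as a conservation diagnostic rather than folded
  into the estimate.

A quantified limitation: percent-of-untreated statistics inherit a small
systematic drift (~0.1–0.5% relative for an isolated band change, a few
percent when the whole profile shifts at high dose) because each
spectrum's vector norm changes when any band changes. This is a property
of full-spectrum normalization itself — present in any analysis of this
design — and bounds how exactly multipliers can be recovered through the
percent route. Ratio statistics do not suffer from it.

## Chemometrics

* **NIPALS PCA**: sequential power iteration with deflation on the
  mean-centered matrix; convergence when the relative score-vector change
  drops below 10⁻⁹ (configurable), max 1000 iterations per component with
  a warning and partial model on non-convergence (noise components with
  near-degenerate eigenvalues legitimately converge slowly). Sign
  convention: each loading's largest-magnitude element is positive. On
  matrices with distinct singular values the model equals the truncated
  SVD up to sign (tested on 50 random matrices at 10⁻⁶).
* **Hotelling's T²** over the k retained scores,
  T²ᵢ = Σⱼ tᵢⱼ²/λⱼ with λⱼ the (n−1) score variance, control limit
  k(n−1)/(n−k)·F(1−α; k, n−k).
* **LDA on PC scores** with two classifier kinds: *linear* (Mahalanobis
  distance under the pooled within-class covariance) and *mahalanobis*
  (per-class covariances; falls back to pooled with a warning when a
  class has ≤ m training samples). Equal priors by default (balanced
  designs). Near-singular covariances are ridge-regularized with
  λ = 10⁻⁸·trace/m, logged. Train/test split is stratified random, 2/3
  train by default, driven by the seed.
* **Default dimensionality**: k = min(10, rank) components; the number m
  of scores fed to LDA defaults to min(10, k) *further capped at half the
  pooled-covariance degrees of freedom* (training samples minus classes).
  Without the cap, 10-dimensional distances estimated from 12 training
  samples are dominated by noise directions and occasionally misclassify
  held-out samples even for well-separated groups; the cap keeps the
  metric well conditioned at the small n typical of replicated
  spectroscopy. Both accuracies — held-out and all-samples — are always
  reported, since published "100% accuracy" claims rarely state which one
  they are.

## Statistics

Group results are mean ± SEM (n−1 sd). Comparisons against untreated use
a two-tailed unpaired t test — Student pooled-variance by default
(matching the historical default of the software such studies use), Welch
optional — with star tiers at closed boundaries p ≤ 0.05/0.01/0.001/
0.0001. No multiple-testing correction is applied by default, mirroring
field practice for this analysis; a Benjamini–Hochberg-style correction
is out of scope. The experimental unit is configurable: by default
technical replicates are averaged within their biological replicate
(n = number of biological replicates); `unit="technical"` treats every
spectrum as independent (n = 9 in the default design), which is what the
generator's significance calibration targets.

## Numerical conventions and degenerate inputs

Wavenumber windows are closed intervals with a 10⁻⁹-relative tolerance so
on-grid endpoints are always included. Zero-norm spectra, flat spectra,
references without structure in the flatten window, missing untreated
groups, zero ratio denominators and contradictory config regions all
raise typed `ValueError` subclasses before any output is written. The
zero-variance test in PCA is relative to the matrix's total sum of
squares, so centering numerically identical rows is correctly detected as
degenerate. Full runs are reproducible: the run manifest records the
config hash, seed, package versions and SHA-256 of every output file, and
identical config+seed gives identical manifests.

## Problem sizes

The bundled tests and the acceptance script run entirely on generated
data at the study's own design sizes: 18–45 spectra of 3351 points per
experiment, 20-seed repetitions for classification summaries, 2000
simulated null comparisons for t-test calibration. A full test run takes
well under a minute on one core.
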