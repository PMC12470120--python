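# Methods

This note documents the models, the numerical choices, and what the
synthetic tests do and do not demonstrate.

## Preprocessing chain

The chain is strictly ordered — QC → baseline → alignment → resampling →
normalization → averaging — and each spectrum carries a `stage` attribute
that each step asserts, so stages cannot be skipped or repeated. The whole
chain is deterministic: identical input produces bit-identical output.

**Quality gate.** An acquisition is kept when the reference band inside
the QC window (990–1012 cm⁻¹, which contains the phenylalanine band)
rises at least `qc_min_snr` (default 3) robust-noise units above the
window's 20 cm⁻¹ flanks. The signal is the window maximum of a 5-point
moving average minus the flank median; the noise scale is the flank
MAD × 1.4826. The light smoothing matters for calibration: the raw
maximum of ~20 independent noise points sits near 2 noise SDs by chance,
so an unsmoothed gate at 3 SDs would pass pure noise roughly 10% of the
time, while the smoothed gate passes it well under 5% (verified by
simulation in the test suite).

**Baseline.** The fluorescence background is modeled as a degree-3
polynomial (degree configurable). The default `iterative_masked` fit
excludes points lying more than 2 robust sigmas (MAD of the currently
masked residuals) above the current fit and refits, iterating until the
mask is stable (≤ 50 rounds). On a noise-free cubic-plus-peak input this
recovers the background exactly and preserves the analytic peak area;
simple clip-to-fit iterations were rejected because they sink the
baseline below the true background (the lower-envelope bias) and distort
peak areas by tens of percent. A `plain_ls` mode (one unmasked least
squares fit) is retained to mirror naive background subtraction.
Corrected intensities may legitimately be negative.

**Alignment.** A rigid axis shift (no warping). The apex of the QC-window
peak is refined by a 3-point parabolic interpolation around the discrete
maximum; the axis is shifted so the apex lands on `align_reference`.
Shifts beyond 10 cm⁻¹ indicate miscalibration and raise an error. The
default reference is **1003 cm⁻¹**, the phenylalanine band position in
the band-assignment literature, so that the aligned frame preserves every
band's tabulated position and the fixed 910.75–930.13 cm⁻¹ integration
window stays centered on the 920 cm⁻¹ lactic-acid band. Instrument
software that nominally aligns the reference band to 1000 cm⁻¹ can be
mirrored by setting `align_reference: 1000.0`; all positions then move
down by ~3 cm⁻¹ coherently.

**Grid and normalization.** Linear interpolation onto 400 + 1.21·k cm⁻¹,
k = 0…966 (967 features, the dimensionality of the classification
matrix; a 969-point variant is reachable by config — the two extra points
are lost to edge effects of alignment). Unit-L2 normalization is the
default; peak-area magnitudes are therefore dimensionless and
config-dependent, and only their group contrasts are meaningful. `area`
and `none` modes exist for sensitivity checks.

**Averaging.** Replicates are averaged pointwise per subject; every
downstream analysis unit is the subject, never the acquisition.

## PCA-LDA diagnosis

PCA is the SVD of the mean-centered subjects × features matrix. The
two-class discriminant is the closed-form Fisher solution
`w ∝ S_w⁻¹(m₁ − m₂)` on the leading k component scores, normalized to
unit length, with a ridge of `1e-8·trace(S_w)` added (and logged) only if
the within-class scatter is numerically singular. Conventions:

- sign: the canonical axis is oriented so the control-class mean score is
  positive (disease scores negative);
- threshold: midpoint of the class mean scores (equal priors);
- error: balanced (unweighted mean of per-class error fractions), so the
  minority class is not discounted;
- component count: smallest k in 1…k_max minimizing the balanced LOOCV
  error (parsimony on ties).

Leave-one-out validation refits the centering, loadings and discriminant
on every fold, so the held-out subject can never leak into its own model;
a fixed-PCA mode exists only for comparison with leaky workflows. The
fold machinery computes one SVD per fold at k_max and reuses the leading
scores for each smaller k, so the full error-vs-k profile costs no more
than a single LOOCV.

ROC uses the held-out canonical scores (negated, so larger = more
disease-like). The area is the Mann–Whitney U of the two score samples
divided by n₁n₂ (ties count one half) and the p-value is the
tie-corrected normal approximation of the rank-sum null, two-sided,
without continuity correction — chosen so degenerate inputs behave
exactly (identical samples give p = 1).

## Biomarker statistics

The 920 cm⁻¹ lactic-acid area is the plain trapezoid of the preprocessed
intensity over 910.75–930.13 cm⁻¹ with endpoints snapped inward to grid
points (bit-reproducible bounds on a fixed grid); an optional local-chord
mode subtracts the straight line between the window endpoints, since
peak-area practice varies. The statistic is linear in the spectrum.

Test conventions: pooled-variance two-sample t by default (Welch by
flag); Mann–Whitney with tie-corrected asymptotic p and no continuity
correction; one-way ANOVA; Shapiro–Wilk for normality (3 ≤ n ≤ 5000).
Severity strata use apnea-hypopnea-index bins [5, 15), [15, 30], (30, ∞)
— both boundary values belong to the moderate class — and obesity strata
use BMI [25, 30) vs ≥ 30, with subjects below 25 excluded and reported.
No multiple-testing correction is applied anywhere; all p-values are
nominal, matching how such exploratory panels are reported.

Spearman correlation uses an exact permutation p-value for n ≤ 9
(enumerating all rank pairings) and the t-approximation above. The
quadratic-lactate screen fits `CV ~ lactate + lactate²` with the
quadratic term built on centered lactate for conditioning (coefficients
are reported in the raw basis), flags points with Cook's distance > 4/n
or |externally studentized residual| > 3, removes them and refits; when
the fit interpolates (near-zero residual variance) nothing is flagged.
The joint model `CV ~ β₁·lactate + β₂·auc920` drops the flagged subjects,
rejects rank-deficient or near-collinear designs (condition number >
1e10), and reports Shapiro–Wilk residual-normality and Breusch–Pagan
homoscedasticity p-values.

## Synthetic cohort generator

The generator's defaults are the study conditions: 51 disease / 34
control subjects, 10 replicates each, severity proportions 14:14:23
(mild [5,15) : moderate [15,30] : severe (30,∞) events/h, drawn uniformly
within bins), and a band library of 22 Lorentzian peaks at the tabulated
saliva positions (Gaussian shapes available). Group effects are
multiplicative on band amplitude: ×1.2–1.35 at 920/957/1030/1444 cm⁻¹,
×0.78 at the control-elevated bands (477, 589, 618, 630, 640, 1517, 1548
cm⁻¹), ×1 elsewhere; the aluminum-substrate band at 1250 cm⁻¹ is
group-neutral by construction so substrate signal can never drive
classification.

Per-subject variability has three layers: a global intensity scale
(lognormal, CV 0.15 — drop geometry and focus), a per-band biological
factor (lognormal, CV 0.25 — composition differences between donors; this
is what keeps the classifier honestly imperfect, with balanced LOOCV
errors around 10–13% and ROC AUC around 0.92–0.95 at the defaults), and a
latent severity score that scales the disease effect multipliers. Each
replicate adds a cubic fluorescence baseline with coefficients drawn from
documented ranges, white Gaussian noise (SD 0.15 a.u. against a 10 a.u.
reference band), and a rigid axis jitter (SD 0.3 cm⁻¹) that the
alignment step must undo.

Lactate concentrations are lognormal per group with (µ, σ) solved in
closed form from the target median and IQR (median = e^µ, IQR =
2·median·sinh(z₀.₇₅σ)); targets are 13.23/20.51 µM (disease) and
37.76/54.04 µM (control). The lactate z-score is coupled to the latent
severity with weight −0.55, producing a positive within-patient
correlation between the canonical variable and lactate of roughly 0.3–0.45
at the defaults while concentrations remain higher in controls — i.e. the
generator deliberately reproduces the discordance between the
spectroscopic 920-band contrast (disease-elevated) and the assay contrast
(control-elevated). Cortisol and SOD3 are disease-elevated lognormals;
BMI, age, sex, sleepiness score and smoking follow simple documented
distributions. All randomness flows from the single config seed.

A null variant (`generate_null_cohort`) sets every multiplier to 1,
removes the coupling and equalizes the covariate distributions, keeping
the labels — used for type-I calibration of the whole pipeline.

**What passing tests show, and what they do not.** The generator shares
the analysis model's band-plus-baseline structure, so end-to-end recovery
demonstrates internal consistency, correct leakage-free validation and
calibrated test levels — not performance on real saliva, whose peak
shapes, baseline families, substrate effects and covariate couplings are
richer than simulated. Magnitudes (peak-area values, AUCs, coefficients)
are config-dependent; only directions and calibration are asserted.

## Problem sizes in the test and acceptance runs

Calibration loops use deliberately small cohorts chosen so each check
carries adequate Monte-Carlo precision: 400 null cohorts of 12/10
subjects × 2 replicates for the t-test level (binomial SE ≈ 1.1% at the
5% level), 20 null cohorts of 18/14 × 3 for the chance-level LOOCV AUC
(SE of the mean ≈ 0.02), and 20 full-size cohorts for the power check.
The acceptance script runs one full-size cohort end to end.

## Known limitations

- No cosmic-ray despiking, smoothing or scatter correction; no vendor
  binary formats or JCAMP-DX.
- The discriminant is strictly two-class; severity is analyzed only
  through stratified univariate tests.
- The quadratic-lactate outlier policy (4/n, |t| > 3) is a reasonable
  convention, not an inference procedure; removed points are always
  reported by id.
- Exact Spearman p-values are limited to n ≤ 9 (factorial enumeration).
- Peak-area magnitudes depend on the normalization convention and are not
  comparable across configs.
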