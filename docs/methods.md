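# Methods

This note documents the statistical machinery of `pubertyage`: the
normative age model, the bias correction that turns its residual into a
timing statistic, the association models, the synthetic-cohort generator
that the test suite runs everything against, and the numerical and design
choices that were genuinely open.

## 1. Normative age model

**Model.** For one sex and feature set, age is modelled additively,
`age ≈ β₀ + Σⱼ fⱼ(xⱼ)`, with each fⱼ a cubic B-spline (default 10 basis
functions per term, knots evenly spaced over the observed feature range).
Identifiability is enforced by column-centering each term's basis (which
removes the constant direction exactly, since B-splines form a partition of
unity) and dropping the all-ones coefficient direction, which would
otherwise be null in both the design and the penalty.

**Penalty.** Smoothness is penalized through second-order *divided*
differences of the spline coefficients with respect to the Greville
abscissae. This choice matters: its null space is exactly the linear
functions, so in the limit λ → ∞ every term collapses to a straight line
and the model reproduces the multiple linear regression on the same
features (a property the test suite checks at λ = 10⁸, where agreement is
~10⁻⁷; far beyond that, floating-point conditioning of the normal
equations dominates).

**Tuning.** Per-term penalties are chosen on a log-spaced grid (default 7
points in [10⁻³, 10³]) by minimizing GCV = n·RSS/(n − edf)², where
edf = tr[(XᵀX + S_λ)⁻¹XᵀX]. The search is coordinate-wise (two sweeps)
followed by one local half-grid-step refinement per term; an exhaustive
Cartesian search is available (`exhaustive=True`) but its cost grows
exponentially in the number of terms. The full (λ-vector, GCV) trace is
retained on the results object. Because XᵀX and Xᵀy are precomputed, each
grid evaluation is a p×p solve, so tuning costs milliseconds even at
n ≈ 2000.

**Degenerate features.** Ordinal PDS items take four values; their basis
is a single cubic interval, capping the term's effective df at 3. Features
with two or three distinct values enter as unpenalized linear terms;
constant features are demoted to null terms with a warning. Out-of-range
values at prediction time are clamped to the training range (splines
extrapolate badly; clamping is the conservative choice).

**Partial dependence.** Each fitted fⱼ is evaluated on an even grid over
the observed range and centered to mean zero; the curve's range serves as a
feature-importance summary.

## 2. Cross-validation and the puberty age gap

TD observations receive out-of-sample predictions from seeded 10-fold
cross-validation; tuning happens inside each training split only (the test
suite verifies fold predictions are bit-identical to refitting without the
held-out fold). A model trained on the complete TD sample scores the
non-TD observations. Because family stratification already keeps a single
observation per family, record-level fold assignment cannot leak siblings
or repeat waves across folds.

Raw residuals (prediction − age) exhibit regression-to-the-mean: young
children are over-predicted and old under-predicted. The correction fits
OLS of raw residual on age over the pooled TD out-of-sample predictions
and subtracts the fitted line from every observation (TD and non-TD). By
OLS orthogonality the corrected gap has exactly zero slope and correlation
with age on the reference set (checked at 10⁻⁸), and a residual pattern
that is purely linear in age is annihilated exactly. The correction is
pooled rather than per fold; the spec's alternative (per-fold) differs
only at O(1/n) and is not implemented separately.

**Evaluation uses raw predictions.** Model performance (Pearson r, MAE,
paired Wilcoxon signed-rank on absolute errors) is computed on the *raw*
out-of-sample predictions. This is deliberate: the corrected gap retains
the true timing signal by design, so a model that captures timing better
has a *larger* corrected residual, and ranking models by corrected-gap
error would invert the comparison. A `use_corrected=True` switch exists
for the alternative reading.

**Linear baseline.** The traditional measure regresses age on the total
PDS score (sum of the sex's items, menarche coded 1/4) per training fold,
using the same seeded folds as the additive model so absolute errors pair
row-for-row, and receives the same RTM correction.

## 3. Signed-rank comparison

The paired Wilcoxon signed-rank test is implemented in-package. Up to 25
nonzero differences the null distribution of W⁺ is computed exactly by
dynamic programming over the doubled midranks (valid under ties, where the
textbook tables are not); above that, a normal approximation with
mean Σr/2 and variance Σr²/4 — algebraically identical to the
tie-corrected n(n+1)(2n+1)/24 − Σ(t³−t)/48 formula — is used. Zero
differences are dropped before ranking (Wilcoxon's original treatment);
`zero_method="pratt"` ranks them first and discards their ranks. Two-sided
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). The test suite checks exact
agreement with full 2ⁿ sign enumeration for n ≤ 10 and with
`scipy.stats.wilcoxon` on tie-free inputs, and calibrates the type-I error
at n = 50 (10,000 null replicates; observed ≈ 0.052 at α = 0.05).

## 4. Association models

`outcome ~ gap + age + (1|site)` is fitted by maximum likelihood — not
REML — so AIC values are comparable across gap models that share the
fixed-effect structure; AIC = 2k − 2ℓ with k counting fixed effects plus
the two variance components. The random-intercept model is fitted by an
in-package profiled-likelihood routine: for a fixed variance ratio
θ = τ²/σ², GLS for β and the ML σ² are closed-form through the
Sherman–Morrison structure of the per-site covariance, leaving a
one-dimensional optimization over log θ. This is exact ML and orders of
magnitude faster than a general mixed-model optimizer — necessary because
the error-control simulation fits ~13,000 mixed models — and the test
suite enforces agreement with `statsmodels.MixedLM` (β, llf, AIC to ~10⁻⁵).
Wald inference uses the normal reference; with ≥ ~450 observations and 21
sites the difference from a t reference is negligible. A single-site input
falls back to OLS with a warning.

Interaction models add a product of mean-centered gap and age, which
decorrelates the product from the main effects and makes the interaction t
invariant to shifting either variable. Covariate sensitivity appends BMI
z-scores, SES (income and education codes) and race/ethnicity indicator
contrasts (against the largest category) as fixed effects.

**Multiplicity.** Benjamini–Hochberg adjusted p-values (step-up, monotone,
capped at 1) are applied within each sex × model family of 11 outcomes by
default; a `global` family spanning the whole suite is available. Within
each sex, the three gap models are fitted on their common complete-case
observation set so AICs compare like with like; the AIC winner per outcome
uses the conventional cutoff of 2.

## 5. Synthetic cohort generator

The generator emulates the structure of a large multi-site adolescent
cohort: `n_families` families (a second sibling with probability 0.15),
4 annual waves by default, baseline age uniform on 9–10, 21 sites, 47%
female.

- **Latent maturation.** Each subject draws a timing offset
  t ~ N(0, 0.75² yr²) and a log-tempo ~ N(0, 0.1²). Maturation at age a is
  logistic((a − μ_sex + t)/s) with midpoints μ_F = 10.8, μ_M = 12.0 and
  scale s = 1.5/exp(tempo) years. Positive offset = earlier development,
  matching the sign of the puberty age gap. The logistic form gives the
  genuinely nonlinear age–puberty relation that distinguishes the additive
  model from the linear baseline.
- **PDS items** threshold maturation at item-specific cutpoints after
  adding N(0, 0.05) ordinal noise; menarche is an absorbing state across
  waves. Items are sex-appropriate (breast development for females; voice
  and facial hair for males).
- **Hormones** are log-linear-plus-saturating in maturation with additive
  collection-context confound terms (time, duration, wake time, exercise,
  caffeine; modest log-scale defaults) and N(0, 0.25) log-scale noise —
  right-skewed and strictly positive by construction. Setting the
  maturation slopes to zero turns hormones into timing-independent noise,
  which is how the hormonal-null association pattern is exercised.
- **Outcomes.** 8 syndrome, 3 broad and 6 DSM-oriented scales on a
  T-score-like scale (mean 50, SD 10): 50 + 10·effect·z_timing + site
  intercept (SD 2) + noise, where half the noise variance is a
  subject-level general-psychopathology factor shared across scales. The
  shared factor yields realistic cross-scale correlation and a TD fraction
  (~56%) close to large cohort studies; the residual SD is scaled so that
  the standardized effect of timing equals `outcome_effect` (default 0.3)
  exactly when site variance is zero. An optional age-moderation slope
  exercises the interaction models.
- **Missingness** is MCAR at `missing_rate` (default 0; the real
  mechanism of cohort studies is unknown and no fidelity is claimed).
  Downstream stages are complete-case.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: informative missingness, measurement invariance
problems in parent-reported PDS, assay batch effects, true hormone
diurnal dynamics (confounds enter additively by construction, so the
cleaning model is correctly specified here and only approximately in
reality), demographic structure beyond coarse race/SES draws, and
attrition.

## 6. Simulation results the suite verifies

All at fixed seeds; sizes chosen to keep the full suite and the
acceptance script within a few minutes on one CPU.

- **Timing recovery:** with timing SD 0.75 yr and ~2000 observations per
  sex (4300 families, two waves, stratified), the combined-model gap
  correlates with the true latent timing at r ≈ 0.83–0.91 across 10 seeds
  (threshold ≥ 0.6).
- **Effect recovery:** the site LMM recovers an injected 0.3 SD
  timing→outcome effect within ±0.05 at n = 4000.
- **Nonlinearity advantage:** the physical additive model's out-of-sample
  MAE is below the linear baseline's in both sexes with Wilcoxon
  p < 10⁻⁴ (n ≈ 2000/sex).
- **Association pattern:** with hormones generated as timing-independent
  noise, physical-gap associations are FDR-significant and positive for
  ≥ 9 of 11 outcomes per sex while hormonal-gap associations are null.
- **Error control:** under a fully null generator (zero timing→outcome
  effect), the fraction of 200 suite runs (n = 1000 each) with any
  FDR-significant association is 0.075 against a bound of
  0.05 + 2·MC-SE ≈ 0.081. The error-control simulation applies BH as one
  suite-wide family: only that scope carries a suite-wide Simes
  guarantee; with six per-sex × model families, the union of six ≈ 5%
  family-wise events is ~18% by construction, a property of scoping, not
  miscalibration (per-test type-I is ≈ 0.05, verified by permutation).

## 7. Known limitations

- GCV can undersmooth in small folds; the coordinate-wise search can in
  principle miss a jointly better λ configuration (the exhaustive option
  exists but is exponential).
- The Wald normal reference is slightly liberal below a few hundred
  observations or with very few sites.
- The TD/non-TD design scores the two groups with slightly different
  models (cross-validated vs full-sample); with outcomes correlated with
  TD membership this can transmit a small artifactual association to any
  gap measure. At the simulated scales the effect is within Monte-Carlo
  noise of nominal calibration, but it is a structural feature of the
  design worth knowing about.
- BMI standardization is internal-empirical (sex × 1-year age bins,
  sparse bins merged), not an external growth-chart reference; it is only
  used as a sensitivity covariate.
- Whether the TD rule is applied per observation (default) or per subject
  across waves is a config switch; the per-observation reading was chosen
  because the partition operates on the already-stratified single
  observation per family.
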