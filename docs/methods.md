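# Methods

This note documents the statistical models the package implements, the
synthetic cohort they are validated on, and the numerical and design
choices a maintainer would want to know.

## Models and procedures

### Biological-age construction

* **Telomere length.** qPCR T/S ratios are batch-adjusted by centring each
  batch on the grand mean (a one-way fixed-effect adjustment — the
  simplest model that removes additive plate offsets). Outliers beyond
  mean ± 4·SD, computed once on the adjusted values, are flagged in a
  single pass; the screen is deliberately not iterated, so the flagged set
  is a fixed function of the data.
* **Epigenetic clocks.** A clock is a frozen linear predictor over CpG
  beta values with an optional monotone output transform (identity by
  default; the transform hook exists for clocks calibrated on a
  log-linear juvenile age scale but ships unused). Application is exact,
  order-invariant, and refuses silently imputing missing CpGs.
* **Physiological age (Klemera–Doubal on principal components).**
  Per sex, a one-row-per-individual training subsample is drawn (seeded);
  biomarkers pass a |Pearson r with chronological age| > 0.10 screen
  (absolute value by default — several clinical markers correlate
  negatively with age in the elderly; a signed variant is a parameter);
  principal components of the standardized markers are screened by the
  same rule; each retained component is regressed on age
  (`x_j = q_j + k_j·CA + ε(s_j)`), and the estimator combines markers and
  age by inverse-variance weighting. The age-uncertainty variance is
  estimated as `s²_BA = max(ε, V − U)` with `V` the training variance of
  `BA_E − CA`, `U = ((1−r²_char)/r²_char)·range(CA)²/(12m)` and
  `r²_char = mean(r_j²)`, `ε = 10⁻⁶·var(CA)`.

  A property of this estimator worth knowing: `U` assumes a uniform age
  distribution (`range²/12 ≥ var(CA)` for bell-shaped ages) and an equal
  information share per component. When PCA concentrates the panel into
  one dominant component, `U` systematically exceeds `V` and `s²_BA`
  floors at `ε`, upon which `BA_EC → CA`: the physiological age becomes
  strongly age-anchored, exactly the behaviour reported for this class of
  composite in real panels. The floor is warned about, never silent. The
  combination-gain property (the composite tracks a latent biological age
  better than any single marker) therefore holds for the marker-only
  estimate `BA_E` (the `s²_BA → ∞` limit), which is what the test suite
  asserts.
* **Cognitive composite.** Tests are z-scored against wave-1 anchors, the
  first principal component is scored with frozen wave-1 coefficients
  (oriented so higher = better performance), and T-scaled to mean 50,
  SD 10 at wave 1. Rows missing any test are missing — PC scoring has no
  defensible partial rule.
* **FAI.** Vision and hearing (1 = best … 5 = worst) are averaged into a
  sensory indicator; sensory, pulmonary, grip, and gait are z-scored
  against wave-2 anchors, oriented so higher = worse functioning
  (pulmonary/grip/gait enter negated), and summed. Orientation signs are
  configurable because self-report scales differ between instruments.
* **FI.** Deficit ratio over 42 items; computed only when ≥ 80% of items
  (34 of 42) are answered, otherwise missing.

### Trajectories and residuals

Each BA is fitted on all its available visits with
`BA = β₀ + ns(CA; 3 df) + β₄·sex + u_pair + u_individual + e`.
The natural cubic spline has interior knots at the 33.3/66.7 age
percentiles and boundary knots at the observed age range (the dominant
convention when only the degrees of freedom are specified); outside the
boundary the basis continues linearly and predictions are flagged as
extrapolation. REML is used for estimation and residuals; the
sex-by-spline interaction is tested by a full-ML likelihood ratio against
χ²₃ (REML likelihoods are not comparable across fixed-effect structures).

Residuals are empirical-Bayes by default: observation − fixed effects −
shrunken pair and individual intercepts. Marginal (fixed-effects-only)
residuals are available via `kind="marginal"`. Each BA is residualized
independently on its own rows; no joint multivariate model is attempted.

The fitter itself (`nested_lmm.NestedLMM`) profiles out the fixed effects
and the residual variance and optimizes the restricted likelihood over
the two variance ratios; the nested-intercept structure admits a closed
Woodbury form, so an evaluation is O(n) in vectorized numpy. This exists
because the calibration studies refit the model thousands of times
(~30 ms per fit instead of ~0.5 s through a general solver); a general
mixed-model implementation fits the identical model and serves as the
independent oracle in the tests, as does a dense-covariance BLUP formula.
Variance-component standard errors come from the numerical Hessian of the
REML criterion in the variance parameters.

### Correlations and clustering

rmcorr removes subject means from both series and correlates the centred
values; this is algebraically the ANCOVA common-slope decomposition
(proved against it to 1e-12 in the tests). df = N − k − 1; p from the t
reference; the CI uses a Fisher z-transform with standard error
1/√(df − 1), the convention matched to these degrees of freedom.
Matrices are computed on complete-measurement visits only, so every cell
uses the same observations. Clustering transforms r to
d² = 2(1 − r) — the squared Euclidean distance between standardized
variables — and applies Ward linkage (scipy, on d; verified against a
hand-coded Lance–Williams update on d²). The 1 − r transform is available
as a parameter.

### Survival

Attained age is the time scale: risk sets are {i : entry_i < t ≤ exit_i},
so age is adjusted for by construction and entry at the baseline
measurement age handles left truncation. Models are stratified by five
10-year birth-cohort bins (anchored at the decade floor of the earliest
birth year), use Efron's tie correction (ages are continuous, ties rare;
the choice is fixed for reproducibility), and report sandwich standard
errors clustered on twin pairs. Predictors are standardized by the mean
and SD over *all* available measurements, then the transform is applied
to baseline values — hazard ratios read per SD of the measure, not per SD
of the baseline distribution. Covariate coding: education as indicators
against "primary" (plus an "unknown" level), smoking against
"non-smoker", BMI linear, sex as the woman-minus-man indicator. The
joint model uses the nine residuals (raw BAs are near-collinear through
their common age trend) on individuals with at least one complete visit,
baseline = first complete visit. Subgroup fits split by sex, by the
median baseline age, or by ever-smoking, dropping the split variable from
the covariates where redundant.

## The synthetic cohort

The generator emulates the design the analysis assumes: ~420 twin pairs
born 1900–1948 (twins share pair id and birth date), up to nine
in-person-testing waves across 1986–2014 (wave 4 is not an in-person
visit), observation window 50–90 years of age, 75% per-wave attendance,
administrative censoring in August 2018. Each BA follows a fixed-effect
age curve (linear for the molecular/physiological measures; a linear
spline with a knot at age 70 and a steeper post-knot slope for the three
functional measures), a woman-minus-man level shift, and pair/individual
random intercepts plus visit noise. Curve levels and dispersions were
chosen to sit at the scale reported for population cohorts of this age
range (e.g. T/S ≈ 0.73, frailty index ≈ 0.10 at age 65, baseline age
≈ 63, 2.5–4.2 visits per person per measure).

Mortality is Gompertz on attained age (hazard 0.013 at age 65, log-slope
0.105/year; a constant-hazard option exists for closed-form checks) with
two proportional-hazards channels per BA: one on the standardized
time-constant latent deviation (pair + individual intercepts) and one on
the standardized visit-level deviation at the first eligible visit. The
second channel exists because empirical-Bayes residualization absorbs
time-constant deviations almost entirely; a "residual-layer" mortality
signal that the joint residual model should detect must therefore live at
the visit level. Death times come from the exact Gompertz inverse
transform conditional on survival to age 50; visits after death are
removed, and individuals dead before their first eligible visit never
enter (this is what makes left truncation real in the simulated data).
Raw measurement layers (CpG panels with stored invertible "true clocks",
biomarkers with shared-latent plus idiosyncratic age structure, cognitive
tests, functional indicators, 42 Bernoulli deficit items, batch-offset
telomere ratios) regenerate each constructor's inputs; administrative
missingness blanks blocks outside their collection waves and for a seeded
subset of individuals per block (methylation ≈ 46% of individuals,
telomere ≈ 75%, mirroring sub-study participation).

What the generator does **not** emulate: co-methylation/LD structure among
CpGs, zygosity-specific twin correlations, covariate confounding (the
simulated education/smoking/BMI are independent of mortality by design,
so adjusted and unadjusted fits agree up to noise), informative
missingness, and measurement-error dependence on age. Passing tests
therefore demonstrate estimator correctness and calibration under the
assumed data-generating structure — not robustness to violations of it.

## Problem sizes used in validation

Calibration studies run at sizes chosen to make their Monte-Carlo error
small relative to the asserted tolerance: variance-component recovery on
500 pairs (~3,300 visits); type-I error of the interaction test over 400
replicates of 100 pairs; Cox CI coverage over 400 replicates of 150
subjects and truncation-bias demonstration over 200 paired replicates;
two-block cluster recovery over 200 replicates of 60 pairs; joint-model
signal isolation over 40 replicates of 300 pairs. The full pipeline runs
at the default 420 pairs.

## Numerical choices and degenerate inputs

* Mixed-model optimization: L-BFGS-B on the two variance ratios with five
  fixed starts, bounds at zero (boundary estimates are legitimate and
  reported as exact zeros), ftol 1e-13. The residual quadratic form is
  computed on the residual vector itself, not by cross-product
  subtraction, for shift invariance.
* Klemera–Doubal: per-component residual SDs are floored at 1e-8 so the
  noise-free calibration identity `BA_EC(x(c), c) = c` stays finite.
* rmcorr refuses series with no within-subject variation and subjects
  with fewer than two complete visits are dropped before anything else.
* Cox fits run Newton–Raphson to a 1e-9 step precision (matching the
  brute-force partial-likelihood oracle to 1e-6 on small data); zero-event
  strata contribute nothing; per-BA failures in batch runs are recorded,
  not fatal.
* Agglomeration ties break toward the lowest-index pair; all report JSON
  is written with sorted keys and rounded floats so identical
  configuration and seed reproduce files byte for byte.

## Known limitations

* The s²_BA floor (above) makes the constructed physiological age nearly
  equal to chronological age on panels whose first principal component
  dominates; this is a property of the published estimator rather than of
  this implementation.
* The frailty-index curve is Gaussian on [0, 1] with clipping; extreme
  tails are slightly distorted relative to a truly bounded model.
* Robust (pair-clustered) errors are asymptotic; at very small cluster
  counts the joint nine-residual model's intervals can be mildly
  anti-conservative.
* The sex-interaction test assumes the same random-intercept structure in
  both models; random slopes are out of scope throughout.
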