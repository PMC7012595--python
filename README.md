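# bioage-panel

Joint longitudinal analysis of multiple biological-age measures (BAs) in a
twin cohort: how nine different BAs — telomere length, four DNA-methylation
clocks, a Klemera–Doubal physiological age, a cognitive composite, a
functional aging index (FAI), and a frailty index (FI) — change with age,
how they correlate with each other once chronological age is removed, and
how each predicts all-cause mortality alone and jointly.

The package is for biostatisticians and ageing researchers who want the
full analysis chain as tested, reusable code: every stage runs end to end
on a seeded synthetic twin cohort with known ground truth, so each
estimator ships with parameter-recovery and calibration evidence.

## The analysis

**Construction.** Each BA is built from its raw measurement block:
batch-centred qPCR T/S ratios with a mean ± 4·SD outlier screen; linear
CpG clocks `DNAmAge = β₀ + Σ wⱼ βⱼ`; the Klemera–Doubal estimator on
principal components of age-screened biomarkers (|r with CA| > 0.1),

```
BA_EC = [ Σⱼ kⱼ(xⱼ − qⱼ)/sⱼ² + CA/s²_BA ] / [ Σⱼ kⱼ²/sⱼ² + 1/s²_BA ]
```

with per-marker regressions `xⱼ = qⱼ + kⱼ·CA + ε(sⱼ)`; a first-principal-
component cognitive T-score (mean 50, SD 10, anchored at wave 1); the FAI
as a sum of four wave-2-standardized functional indicators; and the FI as
the deficit ratio over 42 items.

**Trajectories and residuals.** Each BA is modelled as

```
BA_ijk = β₀ + ns(CA_ijk; 3 df) + β₄·sex_ij + u_i + u_ij + e_ijk
```

a Gaussian mixed model with a natural cubic age spline, a sex level shift,
and nested random intercepts for twin pair (`u_i`) and individual (`u_ij`),
fitted by REML. The *BA residual* — observation minus fixed effects minus
empirical-Bayes intercepts — is the age-acceleration analogue used
downstream. A likelihood-ratio test (full ML, df = 3) probes sex-specific
curve shapes.

**Correlations.** Repeated-measures correlation (rmcorr: Pearson
correlation after removing subject means, df = N − k − 1) among CA and the
BAs and among the residuals, on complete-measurement visits only; Ward
clustering on d² = 2(1 − r).

**Mortality.** Cox models on the attained-age timescale with left
truncation at the baseline measurement age, stratified by 10-year birth
cohort, Efron ties, and pair-clustered robust errors; hazard ratios are
per SD of the measure (SD over all available measurements). One-BA models
(bare and covariate-adjusted) and a joint nine-residual model.

## Worked example

```python
from bioage_panel.pipeline import RunConfig, run_pipeline
out = run_pipeline(RunConfig(seed=1, n_pairs=420, out_dir="run1"))
```

generates a synthetic twin cohort at the default study scale, constructs
the nine BAs from the raw blocks, residualizes, correlates, and fits the
survival models. From `run1/report.json` of that exact run:

```
n_individuals            676
n_measurements           2774
n_complete_measurements  405     (from 143 individuals)
rmcorr mean |r|, BAs     0.826
rmcorr mean |r|, resid   0.061
HR per SD (model 2): grimage 1.48 (1.03, 2.13)   telomere 0.91 (0.80, 1.03)
```

Reading: the nine BAs are strongly inter-correlated (mean |r| ≈ 0.83),
but almost all of that is the shared age signal — after residualization
the mean |r| collapses to ≈ 0.06. The methylation-age analogue built with
a mortality signal (the "grimage" curve) carries a clearly elevated
per-SD hazard while the telomere analogue, simulated with no mortality
effect, is null — the qualitative pattern the analysis is designed to
detect.

The same stages are scriptable from the shell:

```
bioage-panel simulate --seed 1 --out sim/
bioage-panel run --config run.yaml
```

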