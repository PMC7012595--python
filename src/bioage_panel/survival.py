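"""Attained-age Cox models linking baseline biological ages to mortality.

The time scale is attained age: an individual enters the risk set at the
age of their baseline measurement (left truncation) and leaves at death or
censoring age, so chronological age is adjusted for by construction.  All
models are stratified by 10-year birth cohort (separate baseline hazards),
use Efron's tie handling, and report cluster-robust (sandwich) standard
errors with twin pairs as clusters.  Predictors are standardized to SD 1
across *all available measurements* (not baseline values only) so hazard
ratios are per one SD of the measure.

Model 1 is the bare predictor model; Model 2 additionally adjusts for sex,
education, smoking status, and BMI.  One-BA models fit each biological age
separately; the multi-BA model enters all nine *residuals* jointly (raw BAs
are too collinear through their shared age signal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "baseline_extract",
    "standardize_predictors",
    "fit_cox",
    "one_ba_models",
    "nine_ba_model",
    "subgroup_models",
]

EDUCATION_REF = "primary"
SMOKING_REF = "non-smoker"
MODEL2_COVARIATES = ("sex", "education", "smoking", "bmi")


@dataclass
class CoxFit:
    """Hazard ratios with pair-clustered robust confidence intervals."""

    summary: pd.DataFrame          # hr, ci_low, ci_high, se_robust, p per term
    n: int
    n_events: int
    median_followup: float
    log_likelihood: float
    fitter: CoxPHFitter = field(repr=False, default=None)

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def baseline_extract(cohort: pd.DataFrame, ba_col: str,
                     extra_cols: tuple = ()) -> pd.DataFrame:
    """Per-individual baseline (first available) value of one BA.

    The cohort must carry ``exit_age`` and ``event`` columns (constant
    within individual).  Entry age is the chronological age at the first
    visit where the BA is observed; individuals whose exit age does not
    exceed their entry age cannot enter a risk set and are dropped with a
    warning.
    """
    rows = cohort.dropna(subset=[ba_col]).sort_values(
        ["individual_id", "ca"], kind="mergesort")
    base = rows.groupby("individual_id", sort=True).first().reset_index()
    keep = ["individual_id", "pair_id", "sex", "birth_year", "ca", ba_col,
            "exit_age", "event"]
    keep += [c for c in ("birth_stratum", "education", "smoking", "bmi")
             if c in base.columns]
    keep += [c for c in extra_cols if c in base.columns and c not in keep]
    base = base[keep].rename(columns={"ca": "entry_age"})
    bad = base["exit_age"] <= base["entry_age"]
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} individuals with "
                      "exit_age <= entry_age", stacklevel=2)
        base = base.loc[~bad]
    return base.reset_index(drop=True)


def standardize_predictors(values, reference) -> np.ndarray:
    """z = (x - mean(reference)) / sd(reference).

    ``reference`` is typically every available measurement of the variable,
    so the same scale applies to baseline values and hazard ratios read as
    per-SD-of-the-measure.
    """
    reference = np.asarray(reference, dtype=float)
    reference = reference[np.isfinite(reference)]
    sd = reference.std(ddof=1)
    if not sd > 0:
        raise ValueError("reference SD is zero; cannot standardize")
    return (np.asarray(values, dtype=float) - reference.mean()) / sd


def _encode_covariates(df: pd.DataFrame, covariates) -> tuple[pd.DataFrame, list[str]]:
    out = {}
    for cov in covariates:
        if cov == "education":
            levels = [l for l in df["education"].dropna().unique() if l != EDUCATION_REF]
            for lev in sorted(levels):
                out[f"education[{lev}]"] = (df["education"] == lev).astype(float)
        elif cov == "smoking":
            levels = [l for l in df["smoking"].dropna().unique() if l != SMOKING_REF]
            for lev in sorted(levels):
                out[f"smoking[{lev}]"] = (df["smoking"] == lev).astype(float)
        else:
            out[cov] = df[cov].astype(float)
    enc = pd.DataFrame(out, index=df.index)
    return enc, list(enc.columns)


def fit_cox(data: pd.DataFrame, predictors: list[str],
            covariates: tuple = (), strata_col: str = "birth_stratum",
            cluster_col: str = "pair_id", entry_col: str = "entry_age",
            duration_col: str = "exit_age", event_col: str = "event") -> CoxFit:
    """Left-truncated, stratified Cox fit with pair-clustered robust errors.

    ``predictors`` enter as given (standardize upstream); categorical
    covariates are expanded to indicators against their reference levels.
    """
    if not predictors:
        raise ValueError("at least one predictor is required")
    enc, cov_cols = _encode_covariates(data, covariates)
    cols = {c: data[c].astype(float) for c in predictors}
    frame = pd.DataFrame(cols, index=data.index)
    frame = pd.concat([frame, enc], axis=1)
    design = frame.to_numpy(dtype=float)
    if design.shape[1] > 1:
        cond = np.linalg.cond(design - design.mean(axis=0))
        logger.info("fit_cox: predictor condition number %.1f", cond)
    frame[duration_col] = data[duration_col].astype(float)
    frame[event_col] = data[event_col].astype(float)
    frame[entry_col] = data[entry_col].astype(float)
    use_strata = strata_col is not None and strata_col in data.columns
    if use_strata:
        frame[strata_col] = data[strata_col].astype(str)
    use_cluster = cluster_col is not None and cluster_col in data.columns
    if use_cluster:
        frame[cluster_col] = data[cluster_col]
    frame = frame.dropna()

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(frame, duration_col=duration_col, event_col=event_col,
                entry_col=entry_col,
                strata=[strata_col] if use_strata else None,
                cluster_col=cluster_col if use_cluster else None,
                robust=use_cluster,
                fit_options={"precision": 1e-9})
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"], "se_robust": s["se(coef)"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"], "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    followup = frame[duration_col] - frame[entry_col]
    return CoxFit(summary=summary, n=int(len(frame)),
                  n_events=int(frame[event_col].sum()),
                  median_followup=float(followup.median()),
                  log_likelihood=float(cph.log_likelihood_), fitter=cph)


def _per_sd(base: pd.DataFrame, col: str, reference) -> pd.DataFrame:
    base = base.copy()
    base[col] = standardize_predictors(base[col], reference)
    return base


def one_ba_models(cohort: pd.DataFrame, ba_cols: list[str],
                  covariates: tuple = MODEL2_COVARIATES) -> pd.DataFrame:
    """Per-BA Model 1 (bare) and Model 2 (covariate-adjusted) fits.

    Returns a long table with one row per (BA, model): n, deaths, median
    follow-up, HR and CI per SD.  Errors in a single BA fit are recorded
    and do not abort the batch.
    """
    rows = []
    for col in ba_cols:
        try:
            base = baseline_extract(cohort, col)
            base = _per_sd(base, col, cohort[col])
            m1 = fit_cox(base, [col])
            m2 = fit_cox(base, [col], covariates=covariates)
        except Exception as e:   # propagate per BA without aborting the batch
            warnings.warn(f"one-BA model failed for {col}: {e}", stacklevel=2)
            rows.append({"ba": col, "model": "error", "error": str(e)})
            continue
        for label, fit in (("model1", m1), ("model2", m2)):
            rows.append({
                "ba": col, "model": label, "n": fit.n, "deaths": fit.n_events,
                "median_followup": fit.median_followup, "hr": fit.hr(col),
                "ci_low": fit.ci(col)[0], "ci_high": fit.ci(col)[1],
                "se_robust": float(fit.summary.loc[col, "se_robust"]),
                "p": float(fit.summary.loc[col, "p"]),
            })
    return pd.DataFrame(rows)


def nine_ba_model(cohort: pd.DataFrame, resid_cols: list[str],
                  covariates: tuple = MODEL2_COVARIATES) -> dict[str, CoxFit]:
    """Joint model with all BA residuals as simultaneous predictors.

    Restricted to individuals with at least one complete-measurement visit;
    the baseline is the first complete visit.  Residuals (not raw BAs) are
    the predictors to avoid collinearity through the shared age signal.
    Returns {"model1": ..., "model2": ...}.
    """
    if not resid_cols:
        raise ValueError("at least one residual predictor is required")
    complete = cohort.dropna(subset=resid_cols)
    if complete.empty:
        raise ValueError("no complete-measurement visits")
    base = complete.sort_values(["individual_id", "ca"], kind="mergesort") \
        .groupby("individual_id", sort=True).first().reset_index()
    base = base.rename(columns={"ca": "entry_age"})
    base = base.loc[base["exit_age"] > base["entry_age"]].reset_index(drop=True)
    for col in resid_cols:
        base[col] = standardize_predictors(base[col], cohort[col])
    return {
        "model1": fit_cox(base, resid_cols),
        "model2": fit_cox(base, resid_cols, covariates=covariates),
    }


def subgroup_models(cohort: pd.DataFrame, ba_cols: list[str],
                    split: str) -> pd.DataFrame:
    """One-BA Model-2 fits within subgroups (forest-plot-ready table).

    ``split`` is one of "sex" (men/women), "age" (baseline age below/at or
    above the cohort median) or "smoking" (never vs ever smokers).  The
    split variable is removed from the covariate set where redundant.
    Subgroups with no events yield missing rows with a warning.
    """
    rows = []
    for col in ba_cols:
        base = baseline_extract(cohort, col)
        base = _per_sd(base, col, cohort[col])
        if split == "sex":
            groups = {"men": base["sex"] == 0, "women": base["sex"] == 1}
            covs = tuple(c for c in MODEL2_COVARIATES if c != "sex")
        elif split == "age":
            cut = float(base["entry_age"].median())
            groups = {"younger": base["entry_age"] < cut,
                      "older": base["entry_age"] >= cut}
            covs = MODEL2_COVARIATES
        elif split == "smoking":
            ever = base["smoking"].isin(["ex-smoker", "current smoker"])
            groups = {"never": ~ever, "ever": ever}
            covs = tuple(c for c in MODEL2_COVARIATES if c != "smoking")
        else:
            raise ValueError("split must be 'sex', 'age' or 'smoking'")
        for name, mask in groups.items():
            sub = base.loc[mask]
            if sub.empty or sub["event"].sum() == 0:
                warnings.warn(f"subgroup {name} for {col}: no events", stacklevel=2)
                rows.append({"ba": col, "subgroup": name, "n": int(len(sub))})
                continue
            try:
                fit = fit_cox(sub, [col], covariates=covs)
            except Exception as e:
                warnings.warn(f"subgroup {name} for {col} failed: {e}", stacklevel=2)
                rows.append({"ba": col, "subgroup": name, "n": int(len(sub)),
                             "error": str(e)})
                continue
            rows.append({
                "ba": col, "subgroup": name, "n": fit.n, "deaths": fit.n_events,
                "hr": fit.hr(col), "ci_low": fit.ci(col)[0],
                "ci_high": fit.ci(col)[1],
                "p": float(fit.summary.loc[col, "p"]),
            })
    return pd.DataFrame(rows)
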