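"""Long-format cohort table: schema, I/O, validation, covariate handling.

The canonical in-memory representation is a pandas DataFrame with one row per
individual-visit.  Key columns:

``pair_id, individual_id, sex, birth_year, wave, ca``

with ``sex`` coded 0 = man / 1 = woman (all sex coefficients downstream are
woman-minus-man), ``wave`` an in-person-testing index in {1,2,3,5,6,7,8,9,10}
(wave 4 was not an in-person visit and carries no measurements), and ``ca``
the real-valued chronological age in years at the visit.

Measurement blocks are column groups identified by prefix:

=============  =======================================  =================
block          columns                                  construct
=============  =======================================  =================
telomere       ``tl_ts`` (+ ``tl_batch``)               adjusted T/S ratio
methylation    ``cpg_*`` (beta values in [0, 1])        epigenetic clocks
biomarkers     ``bm_*``                                 KDM physiological age
cognitive      ``cog_*`` (percent correct)              first-PC T-score
functional     ``fn_vision fn_hearing fn_pulmonary``    functional aging index
               ``fn_grip fn_gait``
deficits       ``def_01 .. def_42`` (0/1/missing)       frailty index
=============  =======================================  =================

Covariates: ``bmi`` (kg/m^2), ``smoking`` {non-smoker, ex-smoker, current
smoker}, ``education`` {primary, lower secondary or vocational, upper
secondary, tertiary, unknown}.  Survival fields: ``exit_age`` and ``event``
(1 = death), constant within individual.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "VALID_WAVES",
    "KEY_COLUMNS",
    "N_DEFICITS",
    "EDUCATION_LEVELS",
    "SMOKING_LEVELS",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "impute_covariates",
    "assign_birth_strata",
    "block_columns",
]

VALID_WAVES = frozenset({1, 2, 3, 5, 6, 7, 8, 9, 10})
KEY_COLUMNS = ["pair_id", "individual_id", "sex", "birth_year", "wave", "ca"]
N_DEFICITS = 42
EDUCATION_LEVELS = [
    "primary",
    "lower secondary or vocational",
    "upper secondary",
    "tertiary",
    "unknown",
]
SMOKING_LEVELS = ["non-smoker", "ex-smoker", "current smoker"]

BLOCK_PREFIXES = {
    "telomere": ("tl_ts",),
    "methylation": ("cpg_",),
    "biomarkers": ("bm_",),
    "cognitive": ("cog_",),
    "functional": ("fn_",),
    "deficits": ("def_",),
}


class SchemaError(ValueError):
    """Raised when required columns are absent or the column mapping is bad."""


class ValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


def block_columns(df: pd.DataFrame, block: str) -> list[str]:
    """Columns of a measurement block, in table order."""
    try:
        prefixes = BLOCK_PREFIXES[block]
    except KeyError:
        raise KeyError(
            f"unknown measurement block {block!r}; known: {sorted(BLOCK_PREFIXES)}"
        ) from None
    return [
        c for c in df.columns
        if any(c == p or c.startswith(p) for p in prefixes) and c != "tl_batch"
    ]


def _load_schema(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise SchemaError("schema must be a mapping of canonical -> file column names")
    return schema


def read_cohort(path, schema=None) -> pd.DataFrame:
    """Read a long-format cohort CSV and validate it.

    Parameters
    ----------
    path : str or Path
        CSV with a header row; missing values as empty string or "NA".
    schema : dict or YAML path, optional
        Mapping from canonical column names to the file's column names.
        Unmapped canonical names are looked up verbatim.

    Returns
    -------
    DataFrame sorted by (pair_id, individual_id, ca).  Unparseable numeric
    cells become missing; the count is logged.
    """
    mapping = _load_schema(schema)
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True)
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    missing_mapped = [v for v in mapping.values() if v not in df.columns]
    if missing_mapped:
        raise SchemaError(f"mapped columns not in file: {missing_mapped}")
    df = df.rename(columns=rename)

    absent = [c for c in KEY_COLUMNS if c not in df.columns]
    if absent:
        raise SchemaError(f"missing key columns: {absent}")

    n_coerced = 0
    non_numeric = {"pair_id", "individual_id", "smoking", "education", "birth_stratum"}
    for col in df.columns:
        if col in non_numeric:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_coerced += int((coerced.isna() & df[col].notna()).sum())
        df[col] = coerced
    if n_coerced:
        logger.warning("read_cohort: %d unparseable numeric cells set to missing", n_coerced)

    df = df.sort_values(["pair_id", "individual_id", "ca"], kind="mergesort")
    df = df.reset_index(drop=True)
    validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="NA")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants; returns the input on success."""
    absent = [c for c in KEY_COLUMNS if c not in df.columns]
    if absent:
        raise SchemaError(f"missing key columns: {absent}")

    bad_wave = set(df["wave"].dropna().unique()) - VALID_WAVES
    if bad_wave:
        raise ValidationError(
            f"invalid wave values {sorted(bad_wave)}; allowed: {sorted(VALID_WAVES)}"
        )
    if (df["ca"].dropna() <= 0).any():
        raise ValidationError("chronological age must be positive")

    dup = df.duplicated(subset=["individual_id", "wave"])
    if dup.any():
        rows = df.loc[dup, ["individual_id", "wave"]].head()
        raise ValidationError(f"duplicate (individual_id, wave) rows, e.g.\n{rows}")

    for col in ("pair_id", "sex", "birth_year"):
        per_ind = df.groupby("individual_id")[col].nunique(dropna=False)
        if (per_ind > 1).any():
            raise ValidationError(
                f"{col} is not constant within individual_id: "
                f"{per_ind[per_ind > 1].index.tolist()[:5]}"
            )

    def_cols = block_columns(df, "deficits")
    if def_cols and len(def_cols) != N_DEFICITS:
        raise ValidationError(
            f"deficit block has {len(def_cols)} items; expected {N_DEFICITS}"
        )
    cpg_cols = block_columns(df, "methylation")
    if cpg_cols:
        vals = df[cpg_cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValidationError("CpG beta values must lie in [0, 1]")
    if "event" in df.columns:
        ev = df["event"].dropna().unique()
        if not set(ev) <= {0, 1}:
            raise ValidationError(f"event must be 0/1, got {ev}")
    return df


def impute_covariates(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Covariate completion used before survival modelling.

    Missing education anywhere -> the "unknown" category.  Missing BMI or
    smoking at a visit is filled from the same individual's nearest other
    wave by |wave difference|, ties broken toward the earlier wave.
    Individuals with no value at any wave stay missing and are flagged.

    Returns the completed table (copy) and a JSON-able report.
    """
    df = df.copy()
    report = {"education_unknown": [], "flagged_missing": {"bmi": [], "smoking": []}}

    if "education" in df.columns:
        edu = df.groupby("individual_id")["education"].transform(
            lambda s: s.astype("string").ffill().bfill().astype(object)
        )
        all_missing = edu.isna()
        flagged = sorted(df.loc[all_missing, "individual_id"].unique().tolist())
        report["education_unknown"] = flagged
        edu = edu.fillna("unknown")
        df["education"] = edu

    for col in ("bmi", "smoking"):
        if col not in df.columns:
            continue
        missing_mask = df[col].isna()
        if not missing_mask.any():
            continue
        for ind, sub in df[df["individual_id"].isin(df.loc[missing_mask, "individual_id"])].groupby(
            "individual_id"
        ):
            avail = sub.dropna(subset=[col])
            if avail.empty:
                report["flagged_missing"][col].append(ind)
                continue
            for idx in sub.index[sub[col].isna()]:
                target_wave = df.at[idx, "wave"]
                # nearest wave; tie -> earlier wave
                key = (avail["wave"] - target_wave).abs() * 100 + avail["wave"] * 0.01
                donor = avail.loc[key.idxmin()]
                df.at[idx, col] = donor[col]
        report["flagged_missing"][col] = sorted(report["flagged_missing"][col])
    return df, report


def assign_birth_strata(df: pd.DataFrame, n_strata: int = 5, width: int = 10,
                        anchor: float | None = None) -> pd.DataFrame:
    """Assign each individual a 10-year birth-cohort stratum.

    Five decade-wide bins anchored at the decade floor of the minimum birth
    year; these become the baseline-hazard strata of the Cox models.  A
    birth-year span needing more bins raises (pass an explicit ``anchor`` /
    larger ``n_strata`` to override).
    """
    df = df.copy()
    by = df["birth_year"]
    if by.isna().any():
        raise ValidationError("birth_year missing for some rows")
    lo = float(anchor) if anchor is not None else float(np.floor(by.min() / width) * width)
    hi_needed = int(np.floor((by.max() - lo) / width)) + 1
    if hi_needed > n_strata:
        raise ValidationError(
            f"birth-year span {by.min():.0f}-{by.max():.0f} needs {hi_needed} bins of "
            f"width {width} but n_strata={n_strata}; pass explicit bins"
        )
    idx = np.floor((by - lo) / width).astype(int)
    labels = [f"[{lo + width * i:.0f},{lo + width * (i + 1):.0f})" for i in range(n_strata)]
    df["birth_stratum"] = pd.Categorical(
        [labels[i] for i in idx], categories=labels, ordered=True
    )
    return df


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
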