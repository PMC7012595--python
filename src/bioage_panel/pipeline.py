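"""End-to-end orchestration: simulate -> construct -> residualize ->
correlate -> survive, as a configured, seeded, logged run.

Every stage writes plain-table artifacts into the run directory; the run
ends with ``report.json`` (cohort counts, baseline characteristics, key
hazard ratios) and ``provenance.json`` (config, seeds, package version).
A persisted config plus seed reproduces every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import impute_covariates, read_cohort, save_report, validate_cohort
from .constructors import (
    CognitiveComposite,
    EpigeneticClock,
    FunctionalAgingIndex,
    KlemeraDoubalAge,
    adjust_telomere,
    frailty_index,
    screen_biomarkers,
)
from .correlations import cluster_bas, complete_measurements, correlation_matrix
from .simulate import (
    BA_NAMES,
    BLOCK_TO_BA,
    RawLayerSpec,
    default_truth,
    make_missingness,
    simulate_cohort,
)
from .survival import nine_ba_model, one_ba_models, subgroup_models
from .trajectories import add_residual_columns, fit_all_trajectories, sex_interaction_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "baseline_table", "construct_bas"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``input_csv=None`` generates a synthetic cohort; otherwise the CSV is
    read (with optional column-mapping ``schema``).  All module-level knobs
    are surfaced here so a persisted config reproduces the run.
    """

    seed: int = 1
    out_dir: str = "run"
    input_csv: str | None = None
    schema: dict | None = None
    n_pairs: int = 420
    apply_missingness: bool = True
    stages: tuple = ("simulate", "construct", "residualize", "correlate", "survival")
    screening_threshold: float = 0.10
    signed_screen: bool = False
    distance_transform: str = "2(1-r)"
    fi_min_fraction: float = 0.80
    residual_kind: str = "eb"
    drop_blocks: tuple = ()        # measurement blocks to withhold entirely
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _round_floats(obj, ndigits=8):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _dump_json(obj, path):
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True,
                  default=_json_default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# constructing the nine BAs from raw blocks

def construct_bas(cohort: pd.DataFrame, clocks: dict[str, EpigeneticClock],
                  seed: int = 0, screening_threshold: float = 0.10,
                  signed_screen: bool = False,
                  fi_min_fraction: float = 0.80) -> tuple[pd.DataFrame, dict]:
    """Compute every BA whose raw measurement block is present.

    Returns the cohort with ``ba_<name>`` columns (overwritten where
    constructed) plus a dict of the trained constructor objects.
    """
    df = cohort.copy()
    trained: dict = {}
    rng = np.random.default_rng(seed)

    if "tl_ts" in df.columns and df["tl_ts"].notna().any():
        adj, excl = adjust_telomere(df["tl_ts"].to_numpy(),
                                    df.get("tl_batch"))
        adj[excl] = np.nan
        df["ba_telomere"] = adj
        trained["telomere_excluded"] = int(excl.sum())

    for name, clock in clocks.items():
        if all(c in df.columns for c in clock.cpg_ids):
            df[f"ba_{name}"] = clock.predict(df)
            trained[f"clock_{name}"] = clock

    bm_cols = [c for c in df.columns if c.startswith("bm_")]
    if bm_cols and df[bm_cols].notna().any().any():
        out = np.full(len(df), np.nan)
        for sex in (0.0, 1.0):
            sex_rows = df[(df["sex"] == sex) & df[bm_cols].notna().all(axis=1)
                          & df["ca"].notna()]
            # training subsample: one randomly selected visit per individual
            train = sex_rows.groupby("individual_id", sort=True).sample(
                n=1, random_state=int(rng.integers(0, 2 ** 31 - 1)))
            kept = screen_biomarkers(train, train["ca"], bm_cols,
                                     threshold=screening_threshold,
                                     signed=signed_screen)
            if not kept:
                logger.warning("no biomarker passed screening for sex=%s", sex)
                continue
            kdm = KlemeraDoubalAge(pc_threshold=screening_threshold,
                                   signed_screen=signed_screen)
            kdm.fit(train[kept], train["ca"])
            m = df["sex"] == sex
            out[m.to_numpy()] = kdm.predict(df.loc[m, kept], df.loc[m, "ca"])
            trained[f"kdm_sex{int(sex)}"] = kdm
        df["ba_physio"] = out

    cog_cols = [c for c in df.columns if c.startswith("cog_")]
    if cog_cols and df[cog_cols].notna().any().any():
        anchor = df[(df["wave"] == 1)][cog_cols].dropna()
        if len(anchor) >= 3:
            cc = CognitiveComposite().fit(anchor)
            df["ba_cognitive"] = cc.transform(df[cog_cols])
            trained["cognitive"] = cc
        else:
            logger.warning("no wave-1 anchor rows for the cognitive composite")

    fn_cols = ["fn_vision", "fn_hearing", "fn_pulmonary", "fn_grip", "fn_gait"]
    if all(c in df.columns for c in fn_cols) and df[fn_cols].notna().any().any():
        anchor = df[df["wave"] == 2]
        if len(anchor.dropna(subset=fn_cols)) >= 3:
            fai = FunctionalAgingIndex().fit(anchor)
            df["ba_fai"] = fai.transform(df)
            trained["fai"] = fai
        else:
            logger.warning("no wave-2 anchor rows for the functional aging index")

    def_cols = [c for c in df.columns if c.startswith("def_")]
    if def_cols and df[def_cols].notna().any().any():
        df["ba_fi"] = frailty_index(df[def_cols].to_numpy(),
                                    min_fraction=fi_min_fraction)

    return df, trained


# ---------------------------------------------------------------------------
# summary tables

def baseline_table(cohort: pd.DataFrame, ba_cols: list[str]) -> pd.DataFrame:
    """Baseline (first available measurement) characteristics per BA subcohort."""
    rows = {}
    subsets = {"any BA": cohort.dropna(subset=ba_cols, how="all")}
    for col in ba_cols:
        subsets[col] = cohort.dropna(subset=[col])
    for label, sub in subsets.items():
        if sub.empty:
            rows[label] = {k: np.nan for k in
                           ("n", "women_pct", "above_primary_pct", "bmi_mean",
                            "bmi_sd", "ever_smoker_pct", "age_mean", "age_sd",
                            "ba_mean", "ba_sd", "n_meas_mean", "n_meas_sd")}
            continue
        base = sub.sort_values(["individual_id", "ca"], kind="mergesort") \
            .groupby("individual_id", sort=True).first()
        n_meas = sub.groupby("individual_id").size()
        row = {
            "n": int(len(base)),
            "women_pct": 100.0 * float((base["sex"] == 1).mean()),
            "age_mean": float(base["ca"].mean()),
            "age_sd": float(base["ca"].std(ddof=1)),
            "n_meas_mean": float(n_meas.mean()),
            "n_meas_sd": float(n_meas.std(ddof=1)),
        }
        if "education" in base.columns:
            row["above_primary_pct"] = 100.0 * float(
                base["education"].isin(
                    ["lower secondary or vocational", "upper secondary",
                     "tertiary"]).mean())
        if "bmi" in base.columns:
            row["bmi_mean"] = float(base["bmi"].mean())
            row["bmi_sd"] = float(base["bmi"].std(ddof=1))
        if "smoking" in base.columns:
            row["ever_smoker_pct"] = 100.0 * float(
                base["smoking"].isin(["ex-smoker", "current smoker"]).mean())
        if label != "any BA":
            row["ba_mean"] = float(base[label].mean())
            row["ba_sd"] = float(base[label].std(ddof=1))
        rows[label] = row
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# the run

def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    log = []

    def stage_done(name, **info):
        log.append({"stage": name, "wall_s": round(time.time() - t_start, 2), **info})
        logger.info("stage %s done: %s", name, info)

    ledger = None
    if config.input_csv:
        cohort = read_cohort(config.input_csv, schema=config.schema)
        stage_done("load", rows=len(cohort))
    else:
        truth = default_truth(n_pairs=config.n_pairs)
        sim = simulate_cohort(truth, RawLayerSpec(), seed=config.seed,
                              include_raw=True)
        cohort, ledger = sim.cohort, sim.ledger
        if config.apply_missingness:
            cohort = make_missingness(cohort, seed=config.seed)
        if config.drop_blocks:
            cohort = make_missingness(
                cohort, pattern={b: set() for b in config.drop_blocks},
                individual_availability={})
            logger.info("withholding blocks entirely: %s", config.drop_blocks)
        cohort.to_csv(out / "cohort.csv", index=False, na_rep="NA")
        sim.survival.to_csv(out / "survival.csv", index=False, na_rep="NA")
        stage_done("simulate", rows=len(cohort),
                   individuals=int(cohort["individual_id"].nunique()))

    if "construct" in config.stages:
        clocks = {}
        if ledger is not None and ledger.get("raw_layers"):
            for name, d in ledger["raw_layers"]["true_clocks"].items():
                clocks[name] = EpigeneticClock(name, d["cpg_ids"], d["weights"],
                                               d["intercept"])
        cohort, trained = construct_bas(
            cohort, clocks, seed=config.seed,
            screening_threshold=config.screening_threshold,
            signed_screen=config.signed_screen,
            fi_min_fraction=config.fi_min_fraction)
        for key, obj in trained.items():
            if hasattr(obj, "to_json"):
                (out / f"model_{key}.json").write_text(obj.to_json())
        stage_done("construct", constructed=sorted(
            c for c in cohort.columns if c.startswith("ba_")))

    cohort, imput_report = impute_covariates(cohort)
    save_report(imput_report, out / "imputation_report.json")
    validate_cohort(cohort)

    ba_cols = [f"ba_{n}" for n in BA_NAMES if f"ba_{n}" in cohort.columns
               and cohort[f"ba_{n}"].notna().sum() > 0]
    resid_cols = []

    if "residualize" in config.stages:
        usable = [c for c in ba_cols
                  if cohort.dropna(subset=[c])["pair_id"].nunique() >= 2]
        models = fit_all_trajectories(cohort, usable)
        cohort = add_residual_columns(cohort, models, kind=config.residual_kind)
        resid_cols = ["resid_" + c[3:] for c in usable]
        for c, m in models.items():
            (out / f"trajectory_{c}.json").write_text(m.to_json())
        grid = np.linspace(50, 90, 81)
        curves = pd.concat([
            m.population_curve(grid, sex).assign(ba=c)
            for c, m in models.items() for sex in (0, 1)])
        curves.to_csv(out / "curves.csv", index=False)
        lrt = pd.DataFrame([{**sex_interaction_test(cohort, c), "ba": c}
                            for c in usable])
        lrt.to_csv(out / "sex_interaction_lrt.csv", index=False)
        cohort[["pair_id", "individual_id", "wave", "ca"] + resid_cols].to_csv(
            out / "residuals.csv", index=False, na_rep="NA")
        stage_done("residualize", n_models=len(models))

    corr = corr_res = None
    if "correlate" in config.stages and ba_cols:
        corr, dof = correlation_matrix(cohort, ["ca"] + ba_cols)
        corr.to_csv(out / "rmcorr_ba.csv")
        dof.to_csv(out / "rmcorr_ba_df.csv")
        if resid_cols:
            corr_res, dof_res = correlation_matrix(cohort, resid_cols)
            corr_res.to_csv(out / "rmcorr_residuals.csv")
        for name, mat in (("ba", corr.drop(index="ca", columns="ca")),
                          ("residuals", corr_res)):
            if mat is None or mat.isna().any().any():
                logger.warning("skipping %s clustering: missing cells", name)
                continue
            cl = cluster_bas(mat, transform=config.distance_transform)
            (out / f"dendrogram_{name}.nwk").write_text(cl.newick + "\n")
            pd.DataFrame(cl.linkage,
                         columns=["node_a", "node_b", "height", "size"]
                         ).to_csv(out / f"merges_{name}.csv", index=False)
        stage_done("correlate", complete_visits=int(
            len(complete_measurements(cohort, ba_cols))))

    survival_summary = {}
    if "survival" in config.stages and "exit_age" in cohort.columns:
        one = one_ba_models(cohort, ba_cols)
        one.to_csv(out / "cox_one_ba.csv", index=False)
        if resid_cols:
            one_res = one_ba_models(cohort, resid_cols)
            one_res.to_csv(out / "cox_one_ba_residuals.csv", index=False)
            try:
                nine = nine_ba_model(cohort, resid_cols)
                for label, fit in nine.items():
                    fit.summary.to_csv(out / f"cox_nine_ba_{label}.csv")
                survival_summary["nine_ba_model2"] = {
                    k: [round(v, 6) for v in (fit.summary.loc[k, "hr"],
                                              fit.summary.loc[k, "ci_low"],
                                              fit.summary.loc[k, "ci_high"])]
                    for fit in [nine["model2"]] for k in resid_cols}
            except ValueError as e:
                logger.warning("nine-BA model skipped: %s", e)
        subgroups = pd.concat([subgroup_models(cohort, ba_cols, s)
                               .assign(split=s)
                               for s in ("sex", "age", "smoking")])
        subgroups.to_csv(out / "cox_subgroups.csv", index=False)
        ok = one[one["model"] == "model2"].set_index("ba")
        survival_summary["one_ba_model2"] = {
            b: [round(float(ok.loc[b, "hr"]), 6),
                round(float(ok.loc[b, "ci_low"]), 6),
                round(float(ok.loc[b, "ci_high"]), 6)]
            for b in ok.index}
        stage_done("survival", n_models=int(len(one)))

    # report + provenance
    n_complete = int(len(complete_measurements(cohort, ba_cols))) if ba_cols else 0
    chars = baseline_table(cohort, ba_cols)
    chars.to_csv(out / "baseline_characteristics.csv")
    report = {
        "n_individuals": int(cohort["individual_id"].nunique()),
        "n_pairs": int(cohort["pair_id"].nunique()),
        "n_measurements": int(len(cohort)),
        "n_complete_measurements": n_complete,
        "n_complete_individuals": int(
            complete_measurements(cohort, ba_cols)["individual_id"].nunique())
        if ba_cols else 0,
        "ba_columns": ba_cols,
        "baseline": {str(k): _round_floats({kk: (None if pd.isna(vv) else float(vv))
                                            for kk, vv in v.items()})
                     for k, v in chars.iterrows()},
        "survival": survival_summary,
        "correlation_mean_abs": {
            "ba": float(np.nanmean(np.abs(corr.to_numpy()[
                np.triu_indices(len(corr), 1)]))) if corr is not None else None,
            "residuals": float(np.nanmean(np.abs(corr_res.to_numpy()[
                np.triu_indices(len(corr_res), 1)]))) if corr_res is not None else None,
        },
    }
    _dump_json(report, out / "report.json")
    _dump_json({"config": config.to_dict(), "version": __version__,
                "stages_log": [{k: v for k, v in e.items() if k != "wall_s"}
                               for e in log]},
               out / "provenance.json")
    with open(out / "run_log.jsonl", "w") as fh:
        for e in log:
            fh.write(json.dumps(e, default=_json_default) + "\n")
    cohort.to_csv(out / "cohort_final.csv", index=False, na_rep="NA")

    if config.make_figures:
        _make_figures(out, cohort, ba_cols, corr, corr_res)
    return out


def _make_figures(out: Path, cohort, ba_cols, corr, corr_res) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:          # plotting is an optional extra
        logger.warning("matplotlib unavailable; skipping figures")
        return
    if corr is not None:
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(corr)), corr.columns, rotation=90)
        ax.set_yticks(range(len(corr)), corr.columns)
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(out / "heatmap_ba.png", dpi=120)
        plt.close(fig)
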