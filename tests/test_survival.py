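import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from bioage_panel.simulate import default_truth, simulate_cohort
from bioage_panel.survival import (
    baseline_extract,
    fit_cox,
    nine_ba_model,
    one_ba_models,
    standardize_predictors,
    subgroup_models,
)

from helpers import efron_loglik


class TestBaselineExtract:
    def _cohort(self):
        return pd.DataFrame({
            "pair_id": ["P1"] * 2 + ["P1"] * 1 + ["P2"] * 2,
            "individual_id": ["A", "A", "B", "C", "D"],
            "sex": [0, 0, 1, 1, 0],
            "birth_year": [1920] * 5,
            "wave": [3, 6, 5, 2, 2],
            "ca": [66.0, 75.0, 70.0, 63.0, 64.0],
            "ba_fi": [0.1, 0.2, 0.3, np.nan, 0.15],
            "exit_age": [80.0, 80.0, 70.0, 90.0, 66.0],
            "event": [1, 1, 1, 0, 1],
        })

    def test_first_available_measurement_rule(self):
        base = baseline_extract(self._cohort(), "ba_fi")
        a = base.set_index("individual_id")
        assert a.loc["A", "entry_age"] == 66.0
        assert a.loc["A", "ba_fi"] == 0.1

    def test_exit_not_after_entry_dropped(self):
        with pytest.warns(UserWarning, match="exit_age"):
            base = baseline_extract(self._cohort(), "ba_fi")
        # B: measured at 70, exits at 70 -> zero-length interval -> dropped;
        # C has no FI at all
        assert set(base["individual_id"]) == {"A", "D"}

    def test_median_followup_matches_brute_median(self):
        df = pd.DataFrame({
            "entry_age": [60.0, 62.0, 65.0, 66.0, 70.0],
            "exit_age": [75.0, 70.0, 80.0, 81.0, 78.0],
            "event": [1, 0, 1, 1, 0],
            "x": [0.3, -0.2, 0.1, 0.5, -0.4],
        })
        fit = fit_cox(df, ["x"], strata_col=None, cluster_col=None)
        brute = np.median(df["exit_age"] - df["entry_age"])
        assert fit.median_followup == pytest.approx(brute)


class TestStandardization:
    def test_reference_mean_maps_to_zero(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        assert standardize_predictors(ref.mean(), ref) == pytest.approx(0.0)

    def test_log_hr_scales_inversely_with_reference_sd(self):
        rng = np.random.default_rng(0)
        n = 300
        x = rng.normal(0, 1, n)
        entry = rng.uniform(50, 70, n)
        T = entry + rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        df = pd.DataFrame(dict(entry_age=entry, exit_age=T,
                               event=np.ones(n, int)))
        beta = {}
        for sd in (1.0, 2.0):
            d = df.assign(z=x / sd)
            f = fit_cox(d, ["z"], strata_col=None, cluster_col=None)
            beta[sd] = float(f.summary.loc["z", "coef"])
        assert beta[2.0] == pytest.approx(2 * beta[1.0], rel=1e-6)

    def test_all_measurements_vs_baseline_only_reference_differ(self):
        cohort = pd.DataFrame({"ba": [1.0, 5.0, 2.0, 6.0]})
        baseline = np.array([1.0, 2.0])
        z_all = standardize_predictors(baseline, cohort["ba"])
        z_base = standardize_predictors(baseline, baseline)
        assert not np.allclose(z_all, z_base)

    def test_zero_reference_sd_raises(self):
        with pytest.raises(ValueError, match="SD"):
            standardize_predictors([1.0], [2.0, 2.0, 2.0])


class TestCoxAgainstOracle:
    def test_coefficient_matches_efron_partial_likelihood(self):
        rng = np.random.default_rng(7)
        n = 14
        entry = rng.uniform(0, 2, n)
        exit_age = entry + rng.integers(1, 5, n).astype(float)  # ties
        event = rng.integers(0, 2, n)
        event[:5] = 1
        x = rng.normal(0, 1, n)
        df = pd.DataFrame(dict(entry_age=entry, exit_age=exit_age,
                               event=event, x=x))
        fit = fit_cox(df, ["x"], strata_col=None, cluster_col=None)
        beta_hat = float(fit.summary.loc["x", "coef"])
        oracle = minimize_scalar(
            lambda b: -efron_loglik(b, entry, exit_age, event, x),
            bounds=(-4, 4), method="bounded", options={"xatol": 1e-12}).x
        assert beta_hat == pytest.approx(oracle, abs=1e-6)

    def test_stratified_fit_invariant_to_strata_relabeling(self):
        rng = np.random.default_rng(8)
        n = 200
        x = rng.normal(0, 1, n)
        entry = rng.uniform(50, 70, n)
        T = entry + rng.exponential(1 / (0.05 * np.exp(0.3 * x)))
        strat = rng.integers(0, 3, n)
        df = pd.DataFrame(dict(entry_age=entry, exit_age=T, event=1,
                               x=x, birth_stratum=strat.astype(str)))
        a = fit_cox(df, ["x"], cluster_col=None)
        relab = df.assign(birth_stratum=df["birth_stratum"].map(
            {"0": "zz", "1": "aa", "2": "mm"}))
        b = fit_cox(relab, ["x"], cluster_col=None)
        assert float(a.summary.loc["x", "coef"]) == pytest.approx(
            float(b.summary.loc["x", "coef"]), abs=1e-10)

    def test_empty_predictor_list_rejected(self):
        with pytest.raises(ValueError, match="predictor"):
            fit_cox(pd.DataFrame(), [])


class TestOneBAModels:
    def test_counts_match_brute_force(self, masked_cohort):
        tab = one_ba_models(masked_cohort, ["ba_telomere", "ba_fi"])
        for ba in ("ba_telomere", "ba_fi"):
            rows = masked_cohort.dropna(subset=[ba])
            base = rows.sort_values(["individual_id", "ca"]) \
                .groupby("individual_id").first()
            base = base[base["exit_age"] > base["ca"]]
            got = tab[(tab.ba == ba) & (tab.model == "model1")].iloc[0]
            assert got["n"] == len(base)
            assert got["deaths"] == int(base["event"].sum())

    def test_strong_fi_and_null_telomere_pattern(self):
        truth = default_truth(n_pairs=420)
        for name, c in truth.curves.items():
            truth.curves[name] = dataclasses.replace(
                c, log_hr_per_sd=0.8 if name == "fi" else 0.0)
        sim = simulate_cohort(truth, seed=31)
        tab = one_ba_models(sim.cohort, ["ba_fi", "ba_telomere"])
        m2 = tab[tab.model == "model2"].set_index("ba")
        assert m2.loc["ba_fi", "ci_low"] > 1.0
        assert m2.loc["ba_telomere", "ci_low"] < 1.0 < m2.loc["ba_telomere", "ci_high"]


class TestNineBAModel:
    def test_zero_predictors_rejected(self, masked_cohort):
        with pytest.raises(ValueError, match="predictor"):
            nine_ba_model(masked_cohort, [])

    def test_duplicated_signal_splits_between_collinear_predictors(self):
        rng = np.random.default_rng(9)
        n = 2000
        z = rng.normal(0, 1, n)
        x1 = z + 0.3 * rng.normal(0, 1, n)
        x2 = z + 0.3 * rng.normal(0, 1, n)
        entry = rng.uniform(50, 70, n)
        T = entry + rng.exponential(1 / (0.05 * np.exp(0.5 * z)))
        df = pd.DataFrame(dict(entry_age=entry, exit_age=T, event=1,
                               x1=x1, x2=x2))
        single = fit_cox(df, ["x1"], strata_col=None, cluster_col=None)
        joint = fit_cox(df, ["x1", "x2"], strata_col=None, cluster_col=None)
        b_single = float(single.summary.loc["x1", "coef"])
        bj1 = float(joint.summary.loc["x1", "coef"])
        bj2 = float(joint.summary.loc["x2", "coef"])
        assert bj1 < b_single and bj2 < b_single
        assert bj1 > 0 and bj2 > 0


def test_clustered_robust_se_exceeds_naive_under_pair_frailty():
    """With a shared pair-level hazard frailty correlated with the
    predictor, the pair-clustered sandwich SE is larger than the naive
    model-based SE (aggregated over replicates)."""
    ratios = []
    for rep in range(10):
        rng = np.random.default_rng(500 + rep)
        n_pairs = 150
        # predictor largely shared within pair; hazard carries an
        # additional unmodeled pair frailty -> scores correlate within pair
        x_pair = np.repeat(rng.normal(0, 1, n_pairs), 2)
        x = x_pair + 0.3 * rng.normal(0, 1, 2 * n_pairs)
        frailty = np.repeat(rng.normal(0, 1, n_pairs), 2)
        entry = rng.uniform(50, 70, 2 * n_pairs)
        T = entry + rng.exponential(1 / (0.05 * np.exp(0.3 * x + 0.8 * frailty)))
        df = pd.DataFrame(dict(entry_age=entry, exit_age=T, event=1, x=x,
                               pair_id=np.repeat(np.arange(n_pairs), 2)))
        robust = fit_cox(df, ["x"], strata_col=None)
        naive = fit_cox(df, ["x"], strata_col=None, cluster_col=None)
        ratios.append(float(robust.summary.loc["x", "se_robust"])
                      / float(naive.summary.loc["x", "se_robust"]))
    assert np.mean(ratios) > 1.05


class TestSubgroups:
    def test_partition_counts_sum_to_cohort(self, masked_cohort):
        tab = subgroup_models(masked_cohort, ["ba_fi"], split="sex")
        base = baseline_extract(masked_cohort, "ba_fi")
        assert tab["n"].sum() == len(base)

    def test_split_variable_dropped_from_covariates(self, masked_cohort):
        tab = subgroup_models(masked_cohort, ["ba_fi"], split="smoking")
        assert set(tab["subgroup"]) == {"never", "ever"}
        assert tab["hr"].notna().all()
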