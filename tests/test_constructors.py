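import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bioage_panel.constructors import (
    CognitiveComposite,
    EpigeneticClock,
    FunctionalAgingIndex,
    KlemeraDoubalAge,
    adjust_telomere,
    frailty_index,
    screen_biomarkers,
)


class TestTelomereAdjustment:
    def test_exact_batch_offset_removal(self):
        base = np.r_[np.linspace(0.5, 1.0, 20), np.linspace(0.5, 1.0, 20)]
        batches = np.r_[np.zeros(20), np.ones(20)]
        ts = base + np.where(batches == 0, +0.1, -0.1)
        adj, _ = adjust_telomere(ts, batches)
        np.testing.assert_allclose(adj[:20], adj[20:], atol=1e-12)

    def test_four_sd_rule_boundaries(self):
        rng = np.random.default_rng(0)
        ts = rng.normal(0.73, 0.17, 500)
        mu, sd = ts.mean(), ts.std(ddof=1)
        ts = np.append(ts, [mu + 5 * sd, mu + 3.9 * sd])
        _, excl = adjust_telomere(ts)
        assert excl[-2]            # 5 SD out -> excluded
        assert not excl[-1]        # 3.9 SD in -> kept

    def test_single_batch_is_noop(self):
        ts = np.array([0.6, 0.7, 0.8])
        adj, excl = adjust_telomere(ts, np.zeros(3))
        np.testing.assert_array_equal(adj, ts)
        assert not excl.any()

    def test_expected_outlier_count_matches_normal_tail(self):
        """N(0.73, 0.17^2), n=1599: ~ n*P(|Z|>4) ~ 0.1 exclusions per sample."""
        rng = np.random.default_rng(1)
        counts = []
        for _ in range(400):
            ts = rng.normal(0.73, 0.17, 1599)
            _, excl = adjust_telomere(ts)
            counts.append(excl.sum())
        assert np.mean(counts) == pytest.approx(0.101, abs=0.07)


class TestEpigeneticClock:
    def _betas(self, rng, ids, n=10):
        return pd.DataFrame(rng.uniform(0, 1, (n, len(ids))), columns=ids)

    def test_zero_weights_return_intercept(self):
        rng = np.random.default_rng(0)
        clk = EpigeneticClock("flat", ["c1", "c2"], [0.0, 0.0], intercept=60.0)
        np.testing.assert_array_equal(clk.predict(self._betas(rng, ["c1", "c2"])),
                                      np.full(10, 60.0))

    def test_column_order_invariance(self):
        rng = np.random.default_rng(1)
        ids = [f"c{i}" for i in range(8)]
        clk = EpigeneticClock("t", ids, rng.normal(0, 30, 8), 10.0)
        betas = self._betas(rng, ids)
        shuffled = betas[list(reversed(ids))]
        np.testing.assert_allclose(clk.predict(betas), clk.predict(shuffled))

    def test_missing_cpg_and_bad_beta_rejected(self):
        clk = EpigeneticClock("t", ["c1", "c2"], [1.0, 1.0])
        with pytest.raises(KeyError, match="missing"):
            clk.predict(pd.DataFrame({"c1": [0.5]}))
        with pytest.raises(ValueError, match="0, 1"):
            clk.predict(pd.DataFrame({"c1": [0.5], "c2": [1.7]}))

    def test_true_clock_inverts_noise_free_layer(self):
        """The generator's stored clock recovers the latent methylation age
        exactly when CpG noise is zero."""
        from bioage_panel.simulate import RawLayerSpec, simulate_cohort
        sim = simulate_cohort(raw=RawLayerSpec(cpg_noise_sd=0.0), seed=2,
                              include_raw=True)
        spec = sim.ledger["raw_layers"]["true_clocks"]["horvath"]
        clk = EpigeneticClock("horvath", spec["cpg_ids"], spec["weights"],
                              spec["intercept"])
        pred = clk.predict(sim.cohort)
        truth = sim.ledger["latent"]["latent_horvath"]
        # exact except where betas hit the [0,1] clip
        ok = np.abs(pred - truth) < 1e-8
        assert ok.mean() > 0.99

    def test_json_round_trip(self):
        clk = EpigeneticClock("t", ["c1", "c2"], [1.5, -2.0], 30.0)
        again = EpigeneticClock.from_json(clk.to_json())
        betas = pd.DataFrame({"c1": [0.2, 0.8], "c2": [0.9, 0.1]})
        np.testing.assert_allclose(clk.predict(betas), again.predict(betas))


class TestBiomarkerScreen:
    def test_perfect_marker_retained_null_marker_mostly_dropped(self):
        rng = np.random.default_rng(0)
        n = 10_000
        ca = rng.uniform(50, 90, n)
        train = pd.DataFrame({"good": ca + rng.normal(0, 1e-6, n),
                              "noise": rng.normal(0, 1, n)})
        kept = screen_biomarkers(train, ca, ["good", "noise"])
        assert kept == ["good"]

    def test_threshold_is_strict(self):
        # construct a marker with sample correlation exactly 0.10
        rng = np.random.default_rng(1)
        n = 400
        ca = rng.uniform(50, 90, n)
        z_age = (ca - ca.mean()) / ca.std(ddof=1)
        raw = rng.normal(0, 1, n)
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), z_age]), raw,
                                   rcond=None)
        perp = raw - beta[0] - beta[1] * z_age
        perp /= perp.std(ddof=1)
        marker = 0.10 * z_age + np.sqrt(1 - 0.01) * perp
        r = np.corrcoef(marker, ca)[0, 1]
        assert r == pytest.approx(0.10, abs=1e-12)
        assert screen_biomarkers(pd.DataFrame({"m": marker}), ca, ["m"]) == []

    def test_constant_marker_dropped(self):
        ca = np.linspace(50, 90, 50)
        train = pd.DataFrame({"flat": np.ones(50)})
        assert screen_biomarkers(train, ca, ["flat"]) == []

    def test_signed_screen_drops_negative_correlations(self):
        ca = np.linspace(50, 90, 200)
        train = pd.DataFrame({"down": -ca})
        assert screen_biomarkers(train, ca, ["down"], signed=True) == []
        assert screen_biomarkers(train, ca, ["down"], signed=False) == ["down"]


class TestKlemeraDoubal:
    def _noisy_training(self, seed=0, n=500, m=5):
        rng = np.random.default_rng(seed)
        ca = rng.uniform(50, 90, n)
        X = pd.DataFrame({
            f"bm_{j}": 2 + 0.5 * j + ((-1) ** j) * (0.6 + 0.1 * j) * ca
            + rng.normal(0, 5, n) for j in range(m)})
        return X, ca

    def test_noise_free_calibration_identity(self):
        n = 300
        ca = np.linspace(50, 90, n)
        X = pd.DataFrame({f"bm_{j}": 1 + j + (0.5 + 0.2 * j) * ca
                          for j in range(4)})
        kdm = KlemeraDoubalAge().fit(X, ca)
        np.testing.assert_allclose(kdm.predict(X, ca), ca, atol=1e-8)

    def test_pc_regressions_match_normal_equations_oracle(self):
        X, ca = self._noisy_training()
        kdm = KlemeraDoubalAge().fit(X, ca)
        scores = kdm._project(X)
        A = np.column_stack([np.ones_like(ca), ca])
        for j in range(len(kdm.k_)):
            coef, *_ = np.linalg.lstsq(A, scores[:, j], rcond=None)
            assert kdm.q_[j] == pytest.approx(coef[0], abs=1e-10)
            assert kdm.k_[j] == pytest.approx(coef[1], abs=1e-10)
            resid = scores[:, j] - A @ coef
            s = np.sqrt(resid @ resid / (len(ca) - 2))
            assert kdm.s_[j] == pytest.approx(s, abs=1e-10)

    def test_markers_at_expected_values_give_fixed_point(self):
        X, ca = self._noisy_training(seed=1)
        kdm = KlemeraDoubalAge().fit(X, ca)
        target = np.linspace(55, 85, 7)
        scores = kdm.q_[None, :] + kdm.k_[None, :] * target[:, None]
        Z = scores @ kdm.components_
        X_new = pd.DataFrame(Z * kdm.scale_ + kdm.center_,
                             columns=kdm.feature_names_in_)
        np.testing.assert_allclose(kdm.predict(X_new, target), target, atol=1e-8)

    def test_marker_only_limit_single_pc(self):
        """With one retained component, BA_E is the inverse regression."""
        rng = np.random.default_rng(4)
        ca = rng.uniform(50, 90, 300)
        X = pd.DataFrame({"only": 5 + 0.9 * ca + rng.normal(0, 3, 300)})
        kdm = KlemeraDoubalAge().fit(X, ca)
        scores = kdm._project(X)[:, 0]
        expected = (scores - kdm.q_[0]) / kdm.k_[0]
        np.testing.assert_allclose(kdm.predict(X), expected, atol=1e-9)

    def test_refit_reproducibility_and_json(self):
        X, ca = self._noisy_training(seed=2)
        a = KlemeraDoubalAge().fit(X, ca)
        b = KlemeraDoubalAge().fit(X, ca)
        np.testing.assert_array_equal(a.predict(X, ca), b.predict(X, ca))
        c = KlemeraDoubalAge.from_json(a.to_json())
        np.testing.assert_allclose(a.predict(X, ca), c.predict(X, ca), atol=1e-10)

    def test_missing_marker_gives_missing_prediction(self):
        X, ca = self._noisy_training(seed=3)
        kdm = KlemeraDoubalAge().fit(X, ca)
        X2 = X.head(5).copy()
        X2.iloc[0, 0] = np.nan
        out = kdm.predict(X2, ca[:5])
        assert np.isnan(out[0]) and np.isfinite(out[1:]).all()

    def test_combination_gain_over_single_markers(self):
        """The marker-combination estimate tracks the latent age better than
        any single biomarker (n=1000, default noise)."""
        rng = np.random.default_rng(5)
        n = 1000
        ca = rng.uniform(50, 90, n)
        latent = ca + rng.normal(0, 5, n)      # true biological age
        X = pd.DataFrame({f"bm_{j}": (0.5 + 0.1 * j) * latent
                          + rng.normal(0, 6, n) for j in range(6)})
        kdm = KlemeraDoubalAge().fit(X, ca)
        ba_e = kdm.predict(X)
        r_comb = np.corrcoef(ba_e, latent)[0, 1]
        r_single = max(abs(np.corrcoef(X[c], latent)[0, 1]) for c in X)
        assert r_comb > r_single


class TestCognitiveComposite:
    def _anchor(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, 1, n)
        return pd.DataFrame({t: 60 + 8 * g + rng.normal(0, 4, n)
                             for t in ("verbal", "spatial", "memory", "speed")})

    def test_anchor_means_score_fifty(self):
        anchor = self._anchor()
        cc = CognitiveComposite().fit(anchor)
        at_means = pd.DataFrame([anchor.mean()])
        assert cc.transform(at_means)[0] == pytest.approx(50.0, abs=1e-9)

    def test_one_anchor_pc_sd_scores_sixty(self):
        anchor = self._anchor(1)
        cc = CognitiveComposite().fit(anchor)
        z = cc.coef_ * cc.pc_sd_ / float(cc.coef_ @ cc.coef_)
        row = pd.DataFrame([anchor.mean() + z * anchor.std(ddof=1)])
        t = cc.transform(row)[0]
        assert t == pytest.approx(60.0, abs=1e-6)

    def test_two_test_coefficients_match_eigen_oracle(self):
        rng = np.random.default_rng(2)
        g = rng.normal(0, 1, 50)
        tests = pd.DataFrame({"a": g + rng.normal(0, 0.5, 50),
                              "b": g + rng.normal(0, 0.8, 50)})
        cc = CognitiveComposite().fit(tests)
        # correlation matrix [[1, r], [r, 1]]: first eigenvector (1,1)/sqrt(2)
        np.testing.assert_allclose(cc.coef_, [1 / np.sqrt(2), 1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_partial_missing_row_gives_nan(self):
        anchor = self._anchor(3)
        cc = CognitiveComposite().fit(anchor)
        row = pd.DataFrame([anchor.iloc[0]])
        row.iloc[0, 2] = np.nan
        assert np.isnan(cc.transform(row)[0])


class TestFunctionalAgingIndex:
    def _anchor(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "fn_vision": rng.integers(1, 6, n).astype(float),
            "fn_hearing": rng.integers(1, 6, n).astype(float),
            "fn_pulmonary": rng.normal(3.0, 0.5, n),
            "fn_grip": rng.normal(30.0, 4.0, n),
            "fn_gait": rng.normal(1.2, 0.2, n),
        })

    def test_anchor_means_score_zero(self):
        anchor = self._anchor()
        fai = FunctionalAgingIndex().fit(anchor)
        at_means = pd.DataFrame([anchor.mean()])
        assert fai.transform(at_means)[0] == pytest.approx(0.0, abs=1e-9)

    def test_one_sd_worse_on_each_indicator_scores_four(self):
        anchor = self._anchor(1)
        fai = FunctionalAgingIndex().fit(anchor)
        ind = fai._indicators(anchor)
        worse = ind.mean() + ind.std(ddof=1) * pd.Series(
            {"sensory": +1, "pulmonary": -1, "grip": -1, "gait": -1})
        row = pd.DataFrame([{
            "fn_vision": worse["sensory"], "fn_hearing": worse["sensory"],
            "fn_pulmonary": worse["pulmonary"], "fn_grip": worse["grip"],
            "fn_gait": worse["gait"]}])
        assert fai.transform(row)[0] == pytest.approx(4.0, abs=1e-9)

    def test_faster_gait_lowers_the_index(self):
        anchor = self._anchor(2)
        fai = FunctionalAgingIndex().fit(anchor)
        slow = pd.DataFrame([anchor.mean()])
        fast = slow.copy()
        fast["fn_gait"] += 0.5
        assert fai.transform(fast)[0] < fai.transform(slow)[0]

    def test_missing_indicator_gives_nan(self):
        anchor = self._anchor(3)
        fai = FunctionalAgingIndex().fit(anchor)
        row = pd.DataFrame([anchor.mean()])
        row["fn_grip"] = np.nan
        assert np.isnan(fai.transform(row)[0])


class TestFrailtyIndex:
    def test_ratio_cases(self):
        v = np.zeros(42)
        v[:21] = 1
        assert frailty_index(v)[0] == pytest.approx(0.5)
        assert frailty_index(np.zeros(42))[0] == 0.0
        v2 = np.zeros(42)
        v2[:5] = 1
        v2[40:] = np.nan
        assert frailty_index(v2)[0] == pytest.approx(5 / 40)

    def test_minimum_answered_policy(self):
        v = np.full(42, np.nan)
        v[:34] = 0
        assert frailty_index(v)[0] == 0.0
        v[33] = np.nan                      # 33 answered < 34 -> missing
        assert np.isnan(frailty_index(v)[0])

    def test_wrong_length_and_bad_values_rejected(self):
        with pytest.raises(ValueError, match="42"):
            frailty_index(np.zeros(41))
        bad = np.zeros(42)
        bad[0] = 2.0
        with pytest.raises(ValueError, match="0, 1"):
            frailty_index(bad)

    @given(st.lists(st.sampled_from([0.0, 1.0]), min_size=42, max_size=42),
           st.integers(min_value=0, max_value=41))
    def test_bounds_and_monotonicity(self, items, flip):
        v = np.array(items)
        fi = frailty_index(v)[0]
        assert 0.0 <= fi <= 1.0
        w = v.copy()
        w[flip] = 1.0                       # adding a deficit never lowers FI
        assert frailty_index(w)[0] >= fi - 1e-12
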