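"""SMOTE, boosted models, evaluation statistics and adjusted regression."""

import numpy as np
import pandas as pd
import pytest

from habitatomics.models import (
    attribution,
    auc_mann_whitney,
    evaluate,
    fit_boosted,
    harrell_cindex,
    km_logrank,
    multivariable_adjusted,
    smote_oversample,
    youden_cutoff,
)
from habitatomics.synth import CohortSpec, simulate_outcomes
from oracles import cindex_brute


class TestSMOTE:
    def test_synthetic_rows_on_neighbor_segments(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = np.r_[np.ones(6, int), np.zeros(34, int)]
        Xb, yb = smote_oversample(X, y, k=3, seed=1)
        minority = X.iloc[:6].to_numpy()
        synth = Xb.to_numpy()[40:]
        for s in synth:
            # s = x + u (z - x) for some minority pair (x, z): collinearity
            ok = False
            for i in range(6):
                for j in range(6):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    t = (s - minority[i]) @ d / (d @ d)
                    if 0 <= t <= 1 and np.allclose(minority[i] + t * d, s, atol=1e-8):
                        ok = True
            assert ok

    def test_balanced_class_counts(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 3)))
        y = np.r_[np.ones(8, int), np.zeros(42, int)]
        _, yb = smote_oversample(X, y, seed=0)
        counts = np.bincount(yb)
        assert counts[0] == counts[1]

    def test_minority_singleton_rejected(self):
        X = pd.DataFrame(np.zeros((5, 2)))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            smote_oversample(X, y)


class TestBoosted:
    def test_separable_data_training_auc_one(self):
        X = pd.DataFrame({"f": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        bundle = fit_boosted(X, y, "binary", seed=0, tune=False)
        assert auc_mann_whitney(bundle.radscore(X), y) == 1.0

    def test_permuted_labels_cv_auc_near_half(self):
        """Null calibration: mean cross-validated AUC over permuted-label
        datasets (n=300, 5-fold) sits near chance."""
        from sklearn.model_selection import StratifiedKFold

        aucs = []
        for ds in range(3):
            rng = np.random.default_rng(ds)
            X = pd.DataFrame(
                rng.normal(size=(300, 10)), columns=[f"f{i}" for i in range(10)]
            )
            y = rng.permutation(np.r_[np.ones(150, int), np.zeros(150, int)])
            for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
                b = fit_boosted(X.iloc[tr], y[tr], "binary", seed=0, tune=False)
                aucs.append(auc_mann_whitney(b.radscore(X.iloc[te]), y[te]))
        assert 0.42 <= np.mean(aucs) <= 0.58

    def test_two_group_hazard_recovery_matches_risk_oracle(self):
        """Planted 2-group HR=3: the boosted Cox model's held-out
        concordance approaches the true-risk oracle (about 0.62 for a
        balanced binary marker under the 1/2-credit tie convention)."""
        rng = np.random.default_rng(3)
        feats = pd.DataFrame({"g": rng.integers(0, 2, 600).astype(float)})
        spec = CohortSpec(dfs_coefficients={"g": np.log(3.0)}, censoring_rate=0.5, seed=4)
        out = simulate_outcomes(feats, spec)
        tr, te = np.arange(300), np.arange(300, 600)
        bundle = fit_boosted(feats.iloc[tr], out.iloc[tr], "cox", seed=0, tune=False)
        t_te = out["time"].to_numpy()[te]
        e_te = out["event"].to_numpy()[te]
        c_model = harrell_cindex(bundle.radscore(feats.iloc[te]), t_te, e_te)
        c_oracle = harrell_cindex(feats["g"].to_numpy()[te], t_te, e_te)
        assert c_oracle > 0.58  # the marker carries real signal
        assert c_model >= c_oracle - 0.02

    def test_no_events_rejected(self):
        feats = pd.DataFrame({"x": np.zeros(10)})
        out = pd.DataFrame({"time": np.ones(10), "event": np.zeros(10, int)})
        with pytest.raises(ValueError):
            fit_boosted(feats, out, "cox")

    def test_nonfinite_features_rejected(self):
        X = pd.DataFrame({"f": [1.0, np.nan, 2.0]})
        with pytest.raises(ValueError):
            fit_boosted(X, np.array([0, 1, 0]), "binary")


class TestEvaluate:
    def test_perfectly_ranked_auc_one(self):
        res = evaluate(np.arange(20.0), np.r_[np.zeros(10, int), np.ones(10, int)], "auc", n_boot=50)
        assert res["estimate"] == 1.0

    def test_cindex_matches_brute_force_pairs(self):
        rng = np.random.default_rng(5)
        risk = rng.normal(size=30)
        time = rng.exponential(5, 30)
        event = rng.integers(0, 2, 30)
        event[0] = 1
        got = harrell_cindex(risk, time, event)
        want = cindex_brute(risk, time, event)
        assert got == pytest.approx(want, abs=1e-12)

    def test_auc_antisymmetry(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        assert auc_mann_whitney(-scores, y) == pytest.approx(
            1 - auc_mann_whitney(scores, y)
        )

    def test_default_bootstrap_count_is_1000(self):
        import inspect

        assert inspect.signature(evaluate).parameters["n_boot"].default == 1000

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=80) + np.r_[np.zeros(40), np.ones(40)]
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        res = evaluate(scores, y, "auc", n_boot=200, seed=0)
        assert res["ci_lower"] <= res["estimate"] <= res["ci_upper"]


class TestKMLogrank:
    def test_no_events_survival_stays_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.zeros(4, int)
        res = km_logrank(t, e, np.array([0, 0, 1, 1]))
        for curve in res["curves"].values():
            assert (curve.to_numpy() == 1.0).all()
        assert res["chi2"] == 0.0

    def test_duplicated_group_chi2_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        res = km_logrank(t, e, np.array([0, 0, 0, 1, 1, 1]))
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_textbook_table_hand_computed_statistic(self):
        """Times 1,2,3 (group 0, all events) vs 4,5,6 (group 1, all events).

        Hand O-E table for group 0: E = 3/6 + 2/5 + 1/4 = 1.15, O = 3,
        V = 45/180 + 24/100 + 9/48 = 0.6775 -> chi2 = 1.85^2 / 0.6775.
        """
        t = np.arange(1.0, 7.0)
        e = np.ones(6, int)
        res = km_logrank(t, e, np.array([0, 0, 0, 1, 1, 1]))
        assert res["chi2"] == pytest.approx(1.85**2 / 0.6775, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(np.ones(3), np.ones(3, int), np.zeros(3))


class TestYouden:
    def test_separated_scores_unit_youden(self):
        cut, j = youden_cutoff(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert j == 1.0
        assert 0.2 < cut <= 0.8
        cut2, _ = youden_cutoff(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert cut == cut2

    def test_null_scores_small_youden(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(size=2000)
        labels = rng.integers(0, 2, 2000)
        _, j = youden_cutoff(scores, labels)
        assert j < 0.15

    def test_constant_scores_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            _, j = youden_cutoff(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))
        assert j == 0.0


class TestMultivariable:
    def test_contingency_table_odds_ratio(self):
        """2x2 table a=20, b=80, c=5, d=95 -> OR = 20*95/(80*5) = 4.75."""
        y = np.r_[np.ones(20), np.zeros(80), np.ones(5), np.zeros(95)]
        x = np.r_[np.ones(100), np.zeros(100)]
        mv = multivariable_adjusted(None, pd.DataFrame({"x": x}), y, "binary")
        assert mv.loc["x", "OR"] == pytest.approx(4.75, abs=1e-6)

    def test_null_covariate_wald_coverage(self):
        rng = np.random.default_rng(9)
        hits = 0
        reps = 30
        for _ in range(reps):
            x = rng.normal(size=500)
            y = rng.integers(0, 2, 500)
            mv = multivariable_adjusted(None, pd.DataFrame({"x": x}), y, "binary")
            coef = mv.loc["x", "coef"]
            se = (np.log(mv.loc["x", "ci_upper"]) - np.log(mv.loc["x", "ci_lower"])) / (
                2 * 1.959964
            )
            if abs(coef) < 3 * se:
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_cox_toy_matches_partial_likelihood_grid(self):
        """n=4, x=(1,0,1,0), times 1..4 all events: grid-search maximum of
        the exact partial likelihood equals the Newton fit."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, int)
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def pl(beta):
            ll = 0.0
            risk = np.exp(beta * x)
            for i in np.argsort(t):
                ll += beta * x[i] - np.log(risk[t >= t[i]].sum())
            return ll

        grid = np.linspace(-4, 4, 80001)
        beta_grid = grid[np.argmax([pl(b) for b in grid])]
        mv = multivariable_adjusted(None, pd.DataFrame({"x": x}), {"time": t, "event": e}, "cox")
        assert mv.loc["x", "coef"] == pytest.approx(beta_grid, abs=1e-3)

    def test_separation_raises_informative_error(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(ValueError, match="separation"):
            multivariable_adjusted(None, pd.DataFrame({"x": x}), y, "binary")


class TestAttribution:
    def test_efficiency_contributions_sum_to_margin(self):
        import xgboost as xgb

        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = (X["a"] + 0.5 * X["b"] > 0).astype(int).to_numpy()
        bundle = fit_boosted(X, y, "binary", seed=0, tune=False)
        contrib = attribution(bundle, X)
        margin = bundle.booster.predict(xgb.DMatrix(X), output_margin=True)
        np.testing.assert_allclose(contrib.sum(axis=1), margin, atol=1e-4)

    def test_unused_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(
            {"signal": rng.normal(size=120), "dead": np.zeros(120)}
        )
        y = (X["signal"] > 0).astype(int).to_numpy()
        bundle = fit_boosted(X, y, "binary", seed=0, tune=False)
        contrib = attribution(bundle, X)
        assert np.abs(contrib["dead"]).max() == 0.0

    def test_duplicated_features_share_attribution(self):
        """Two identical informative columns: greedy tree splits allot
        unequal credit (symmetry up to a small factor, not equality), but
        both copies must dominate an uninformative column and jointly
        carry the single-copy attribution."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=300)
        X = pd.DataFrame({"a": x, "b": x.copy(), "noise": rng.normal(size=300)})
        y = (x + 0.3 * rng.normal(size=300) > 0).astype(int)
        bundle = fit_boosted(X, y, "binary", seed=0, tune=False)
        imp = attribution(bundle, X).abs().mean()
        assert imp["a"] > imp["noise"]
        assert imp["b"] > imp["noise"]
        X1 = pd.DataFrame({"a": x, "noise": X["noise"]})
        b1 = fit_boosted(X1, y, "binary", seed=0, tune=False)
        imp1 = attribution(b1, X1).abs().mean()
        assert imp["a"] + imp["b"] == pytest.approx(imp1["a"], rel=0.35)

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = (X["a"] > 0).astype(int).to_numpy()
        bundle = fit_boosted(X, y, "binary", seed=0, tune=False)
        with pytest.raises(ValueError):
            attribution(bundle, X.rename(columns={"b": "c"}))
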