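"""Risk dichotomization, moderated DE, BH, ORA and ssGSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habitatomics.radiogenomics import (
    ExpressionStudy,
    GeneSetCollection,
    bh_adjust,
    dichotomize_risk,
    moderated_de,
    ora_hypergeometric,
    ssgsea,
    ssgsea_group_test,
)
from habitatomics.synth import simulate_expression


class TestDichotomize:
    def test_cutoff_above_max_all_low_risk(self):
        with pytest.warns(UserWarning, match="one risk group"):
            g = dichotomize_risk(np.array([0.1, 0.5, 0.9]), cutoff=1.5)
        assert (g == 0).all()

    def test_boundary_score_is_high_risk(self):
        g = dichotomize_risk(np.array([0.3, 0.5, 0.7]), cutoff=0.5)
        np.testing.assert_array_equal(g, [0, 1, 1])

    def test_bimodal_scores_match_planted_groups(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 200)
        scores = np.where(truth == 1, rng.uniform(0.7, 1.0, 200), rng.uniform(0.0, 0.3, 200))
        np.testing.assert_array_equal(dichotomize_risk(scores, 0.5), truth)


class TestModeratedDE:
    def test_null_runs_rarely_call_degs(self):
        """20 independent null datasets: at least 95% yield 0 DEGs at the
        |log2FC| >= 2, q < 0.05 gate."""
        clean = 0
        for seed in range(20):
            risk = np.repeat([0, 1], 20)
            study, _ = simulate_expression(
                risk, {"S": [f"g{i}" for i in range(30)]}, 500, planted={}, seed=seed
            )
            de = moderated_de(study)
            clean += int(de["deg"].sum() == 0)
        assert clean >= 19

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 12))
        group = np.repeat([0, 1], 6)
        study = ExpressionStudy(pd.DataFrame(X), group)
        de = moderated_de(study, prior_df=0.0)
        a, b = X[:, group == 1], X[:, group == 0]
        t_ref = stats.ttest_ind(a, b, axis=1).statistic
        np.testing.assert_allclose(de["t"], t_ref, rtol=1e-8)

    def test_infinite_prior_df_collapses_variances(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 10))
        study = ExpressionStudy(pd.DataFrame(X), np.repeat([0, 1], 5))
        de = moderated_de(study, prior_df=np.inf)
        # all genes share one variance: t proportional to log2FC
        ratio = de["t"] / de["log2FC"]
        assert ratio.std() / abs(ratio.mean()) < 1e-10

    def test_planted_shift_power(self):
        risk = np.repeat([0, 1], 40)
        sets = {"S": [f"g{i}" for i in range(50)]}
        study, _ = simulate_expression(risk, sets, 1000, planted={"S": 3.0}, seed=3)
        de = moderated_de(study)
        assert int(de.loc[sets["S"], "deg"].sum()) >= 45

    def test_zero_variance_gene_p_one_with_warning(self):
        X = np.random.default_rng(4).normal(size=(5, 8))
        X[0] = 1.0
        study = ExpressionStudy(pd.DataFrame(X), np.repeat([0, 1], 4))
        with pytest.warns(UserWarning, match="zero-variance"):
            de = moderated_de(study)
        assert de.iloc[0]["p"] == 1.0

    def test_too_few_samples_rejected(self):
        study = ExpressionStudy(pd.DataFrame(np.zeros((3, 3))), np.array([0, 1, 1]))
        with pytest.raises(ValueError):
            moderated_de(study)


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        assert np.isfinite(q[[0, 2]]).all()


class TestORA:
    def test_closed_form_hypergeometric(self):
        """N=20, K=5, n=4, k=3 -> p = [C(5,3)C(15,1)+C(5,4)C(15,0)]/C(20,4)."""
        uni = [f"u{i}" for i in range(20)]
        coll = GeneSetCollection({"A": uni[:5]}, uni)
        deg = uni[:3] + [uni[10]]
        res = ora_hypergeometric(deg, coll)
        assert res.loc["A", "p"] == pytest.approx(155 / 4845, rel=1e-12)
        assert res.loc["A", "overlap"] == 3

    def test_zero_overlap_never_significant(self):
        uni = [f"u{i}" for i in range(30)]
        coll = GeneSetCollection({"A": uni[:5]}, uni)
        res = ora_hypergeometric(uni[20:24], coll)
        assert res.loc["A", "p"] > 0.4
        assert res.loc["A", "q"] > 0.4

    def test_empty_deg_list_p_one(self):
        uni = [f"u{i}" for i in range(10)]
        coll = GeneSetCollection({"A": uni[:3]}, uni)
        res = ora_hypergeometric([], coll)
        assert (res["p"] == 1.0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_for_small_universes(self, seed):
        from math import comb

        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 25))
        K = int(rng.integers(2, N - 2))
        n = int(rng.integers(1, N - 1))
        uni = [f"u{i}" for i in range(N)]
        coll = GeneSetCollection({"A": uni[:K]}, uni)
        deg = list(rng.choice(uni, size=n, replace=False))
        k = len(set(deg) & set(uni[:K]))
        p_enum = sum(
            comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
        ) / comb(N, n)
        res = ora_hypergeometric(deg, coll)
        assert res.loc["A", "p"] == pytest.approx(p_enum, rel=1e-10)


class TestSsGSEA:
    def test_set_covering_all_genes_skipped(self):
        expr = pd.DataFrame(
            np.random.default_rng(7).normal(size=(5, 3)),
            index=[f"g{i}" for i in range(5)],
        )
        coll = GeneSetCollection({"ALL": [f"g{i}" for i in range(5)]}, list(expr.index))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning, match="covers all"):
                ssgsea(expr, coll)

    def test_top_ranked_set_is_maximal_over_all_placements(self):
        """A set occupying the top-k expression ranks scores at least as
        high as every other same-size set (exhaustive enumeration, 20
        genes, k=3)."""
        from itertools import combinations

        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(20)]
        vals = np.sort(rng.normal(size=20))[::-1]  # g0 highest
        expr = pd.DataFrame({"s": vals}, index=genes)
        scores = {}
        for comb_ in combinations(range(20), 3):
            name = "set"
            coll = GeneSetCollection({name: [genes[i] for i in comb_]}, genes)
            scores[comb_] = float(ssgsea(expr, coll).iloc[0, 0])
        top = scores[(0, 1, 2)]
        assert top == max(scores.values())

    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(9)
        col = rng.normal(size=15)
        expr = pd.DataFrame(
            {"a": col, "b": col.copy()}, index=[f"g{i}" for i in range(15)]
        )
        coll = GeneSetCollection({"S": ["g0", "g3", "g7"]}, list(expr.index))
        s = ssgsea(expr, coll)
        assert s.loc["a", "S"] == s.loc["b", "S"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(
            rng.normal(7, 1, size=(30, 4)), index=[f"g{i}" for i in range(30)]
        )
        coll = GeneSetCollection({"S": [f"g{i}" for i in range(5)]}, list(expr.index))
        a = ssgsea(expr, coll)
        b = ssgsea(np.exp(expr / 2.0), coll)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-10)

    def test_group_test_flags_shifted_signature(self):
        """A planted signature is detected; on a fully null dataset the
        same signature is not. (A planted shift also perturbs the ranks
        of out-of-set genes, so the null control needs its own dataset.)"""
        risk = np.repeat([0, 1], 25)
        sets = {"SIG": [f"g{i}" for i in range(20)]}
        study, coll = simulate_expression(risk, sets, 300, planted={"SIG": 2.0}, seed=11)
        res = ssgsea_group_test(ssgsea(study.expr, coll), risk)
        assert res.loc["SIG", "q"] < 0.05
        study0, coll0 = simulate_expression(risk, sets, 300, planted={}, seed=12)
        res0 = ssgsea_group_test(ssgsea(study0.expr, coll0), risk)
        assert res0.loc["SIG", "q"] > 0.05
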