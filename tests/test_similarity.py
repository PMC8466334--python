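"""Factor extraction, SED, pair labelling, pruning, and the Wald GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scentmark import (label_pairs, pca_factor_scores, prune_outliers,
                       sed_matrix, summarize_similarity, wald_glm)
from scentmark.similarity import PairSet, SeparationError, SimilarityError


def make_pairset(same_seds, diff_seds):
    rec = [("a%d" % i, "b%d" % i, s, True) for i, s in enumerate(same_seds)]
    rec += [("c%d" % i, "d%d" % i, s, False) for i, s in enumerate(diff_seds)]
    return PairSet(pairs=pd.DataFrame(
        rec, columns=["sample_a", "sample_b", "sed", "same"]))


def logistic_newton_oracle(x, y, iters=60):
    """Independent Newton–Raphson MLE for logit(P(y=1)) = b0 + b1·x."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(iters):
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        beta = beta + np.linalg.solve(hess, grad)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
    return beta, cov


class TestPca:
    def test_perfectly_correlated_variables_single_factor(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        X = np.column_stack([2.0 * base + j for j in range(6)])
        fm = pca_factor_scores(X)
        assert fm.n_factors == 1
        assert fm.eigenvalues[0] == pytest.approx(6.0, abs=1e-9)
        assert fm.explained_pct == pytest.approx(100.0, abs=1e-9)

    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 6))
        fm = pca_factor_scores(X)
        eigval = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        keep = eigval[eigval > 1]
        assert fm.n_factors == len(keep)
        np.testing.assert_allclose(fm.eigenvalues[:len(keep)], keep, atol=1e-9)
        assert fm.explained_pct == pytest.approx(100 * keep.sum() / 6,
                                                 abs=1e-9)

    def test_scores_have_unit_variance(self):
        rng = np.random.default_rng(3)
        fm = pca_factor_scores(rng.normal(size=(40, 8)))
        np.testing.assert_allclose(fm.scores.std(ddof=1), 1.0, atol=1e-9)

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(4)
        fm = pca_factor_scores(rng.normal(size=(25, 5)))
        L = fm.loadings.to_numpy()
        for k in range(fm.n_factors):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_constant_column_is_error_naming_compound(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)),
                         columns=["a", "b", "flat"])
        X["flat"] = 7.0
        with pytest.raises(SimilarityError, match="flat"):
            pca_factor_scores(X)

    def test_no_eigenvalue_above_one_warns_and_keeps_largest(self, monkeypatch):
        # uncorrelated variables: all correlation eigenvalues are exactly 1,
        # a boundary that float jitter can tip either way, so pin the
        # eigendecomposition to the exact case
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        monkeypatch.setattr(np.linalg, "eigh",
                            lambda R: (np.ones(len(R)), np.eye(len(R))))
        with pytest.warns(UserWarning, match="largest"):
            fm = pca_factor_scores(X)
        assert fm.n_factors == 1


class TestSed:
    def test_closed_forms(self):
        D = sed_matrix(np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]]))
        assert D.iat[0, 1] == pytest.approx(2.0)
        assert D.iat[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(D), 0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(12)
        S = rng.normal(size=(15, 4))
        D = sed_matrix(S).to_numpy()
        for i in range(15):
            for j in range(15):
                assert D[i, j] == pytest.approx(
                    float(((S[i] - S[j]) ** 2).sum()), abs=1e-12)
                assert D[i, j] == D[j, i]


class TestLabelPairs:
    @pytest.mark.parametrize("n_nests,total,same,diff", [
        (1, 1, 1, 0),
        (5, 45, 5, 40),
        (25, 1225, 25, 1200),
    ])
    def test_mark_pair_counts(self, toy_table, n_nests, total, same, diff):
        nests = [f"N{i}" for i in range(n_nests) for _ in (0, 1)]
        sources = ["mark1", "mark2"] * n_nests
        rng = np.random.default_rng(0)
        t = toy_table(rng.uniform(1, 2, size=(2 * n_nests, 3)), nests, sources)
        D = sed_matrix(rng.normal(size=(2 * n_nests, 2)))
        D.index = D.columns = t.areas.index
        ps = label_pairs(D, t.sample_meta, {"mark1", "mark2"},
                         {"mark1", "mark2"})
        assert ps.counts() == {"total": total, "same": same, "different": diff}

    def test_cross_group_pairs(self, toy_table):
        nests = ["N1", "N1", "N1", "N2", "N2", "N2"]
        sources = ["mark1", "mark2", "gland"] * 2
        rng = np.random.default_rng(1)
        t = toy_table(rng.uniform(1, 2, size=(6, 3)), nests, sources)
        D = sed_matrix(rng.normal(size=(6, 2)))
        D.index = D.columns = t.areas.index
        ps = label_pairs(D, t.sample_meta, {"gland"}, {"mark1", "mark2"})
        # 2 glands × 4 marks
        assert ps.counts() == {"total": 8, "same": 4, "different": 4}

    def test_empty_group_is_error(self, toy_table):
        t = toy_table([[1.0], [1.0]], ["N1", "N1"], ["mark1", "mark2"])
        D = sed_matrix(np.zeros((2, 1)))
        D.index = D.columns = t.areas.index
        with pytest.raises(SimilarityError, match="empty"):
            label_pairs(D, t.sample_meta, {"gland"}, {"mark1"})


class TestPrune:
    def test_no_outliers_unchanged(self):
        ps = make_pairset([1.0, 2.0], [2.0, 3.0])
        out = prune_outliers(ps)
        assert out.n == 4 and len(out.pruned) == 0

    def test_hand_quartile_toy(self):
        # {1,2,2,3,100}: Q1=2, Q3=3 (linear interpolation), fence=3+3*1=6
        ps = make_pairset([1.0, 2.0], [2.0, 3.0, 100.0])
        out = prune_outliers(ps, k_iqr=3.0)
        assert out.n == 4
        assert out.pruned["sed"].tolist() == [100.0]
        assert "fence" in out.pruned["reason"].iloc[0]

    def test_too_few_pairs_is_error(self):
        with pytest.raises(SimilarityError, match="at least 4"):
            prune_outliers(make_pairset([1.0], [2.0]))


class TestWaldGlm:
    def test_symmetric_groups_give_zero_statistic(self):
        res = wald_glm(make_pairset([1.0, 3.0], [1.0, 3.0]))
        assert res.beta1 == pytest.approx(0.0, abs=1e-8)
        assert res.W == pytest.approx(0.0, abs=1e-8)

    def test_matches_newton_raphson_oracle(self):
        ps = make_pairset([1.0, 2.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0])
        res = wald_glm(ps)
        x = ps.pairs["sed"].to_numpy()
        y = ps.pairs["same"].to_numpy(dtype=float)
        beta, cov = logistic_newton_oracle(x, y)
        W_oracle = beta[1] ** 2 / cov[1, 1]
        assert res.beta1 == pytest.approx(beta[1], abs=1e-6)
        assert res.W == pytest.approx(W_oracle, abs=1e-6)
        assert res.p == pytest.approx(stats.chi2.sf(W_oracle, 1), abs=1e-6)
        assert res.n == 8

    def test_scale_invariance_of_wald_statistic(self):
        rng = np.random.default_rng(6)
        same = rng.gamma(2, 2, size=30)
        diff = rng.gamma(3, 3, size=200)
        w1 = wald_glm(make_pairset(same, diff)).W
        w2 = wald_glm(make_pairset(7.3 * same, 7.3 * diff)).W
        assert w1 == pytest.approx(w2, rel=1e-6)

    def test_complete_separation_refuses_wald_value(self):
        with pytest.raises(SeparationError, match="separation"):
            wald_glm(make_pairset([1.0, 2.0], [5.0, 6.0, 7.0]))

    def test_single_class_is_error(self):
        with pytest.raises(SimilarityError, match="both"):
            wald_glm(make_pairset([1.0, 2.0], []))


class TestSummaries:
    def test_singleton_class(self):
        s = summarize_similarity(make_pairset([5.0], [1.0, 2.0]))
        assert s["same"] == {"median": 5.0, "min": 5.0, "max": 5.0, "n": 1}

    def test_even_count_median_is_central_mean(self):
        s = summarize_similarity(make_pairset([1.0, 2.0, 3.0, 4.0], [9.0]))
        assert s["same"]["median"] == pytest.approx(2.5)
        assert (s["same"]["min"], s["same"]["max"]) == (1.0, 4.0)

    def test_default_synthetic_run_orders_medians(self, marks_result):
        s = marks_result["summary"]
        assert s["same"]["median"] < s["different"]["median"]
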