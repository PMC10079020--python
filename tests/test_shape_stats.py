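"""PCA, axis randomization, Procrustes ANOVA (RRPP), pairwise contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cranioforge.shape_stats import (
    ProcrustesANOVA,
    ShapePCA,
    axis_significance,
    pairwise_groups,
    pca,
    procrustes_anova,
)


def sequential_anova_oracle(y, blocks):
    """Textbook sequential (Type I) ANOVA by explicit normal equations.

    ``blocks`` is the ordered list of design blocks (without intercept);
    returns per-term F statistics.
    """
    n = y.shape[0]
    X = np.ones((n, 1))
    rss = [float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))]
    ranks = [1]
    for blk in blocks:
        X = np.column_stack([X, blk])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss.append(float(np.sum((y - X @ beta) ** 2)))
        ranks.append(np.linalg.matrix_rank(X))
    df = np.diff(ranks)
    df_res = n - ranks[-1]
    ms_res = rss[-1] / df_res
    ss = -np.diff(rss)
    return (ss / df) / ms_res


class TestPca:
    def test_all_variance_on_first_variable(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=20), np.zeros(20)])
        res = pca(X)
        np.testing.assert_allclose(res.proportion, [1.0, 0.0], atol=1e-12)

    def test_eigenvalue_sum_is_total_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6)) @ np.diag([3, 2, 1, 1, 0.5, 0.1])
        res = pca(X)
        assert res.eigenvalues.sum() == pytest.approx(np.var(X, axis=0, ddof=1).sum())
        assert res.proportion.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 4))
        res = pca(X)
        np.testing.assert_allclose(res.scores @ res.loadings.T, X - X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-10)

    def test_matches_sklearn_eigenvalues(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 7))
        res = pca(X)
        sk = SkPCA().fit(X)
        np.testing.assert_allclose(res.eigenvalues, sk.explained_variance_, atol=1e-10)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 5))
        L = pca(X).loadings
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_rows_with_missing_cells_dropped(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        X[2, 1] = np.nan
        est = ShapePCA().fit(X, ids=[f"s{i}" for i in range(10)])
        assert est.dropped_ids_ == ["s2"]
        assert est.scores_.shape[0] == 9

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            pca(np.zeros((2, 3)))


class TestAxisSignificance:
    def test_dominant_factor_gives_minimum_p(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=(100, 1))
        X = f @ rng.normal(size=(1, 8)) + 0.05 * rng.normal(size=(100, 8))
        p = axis_significance(X, n_perm=99, random_state=0)
        assert p[0] == pytest.approx(1 / 100)

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(7)
        p = axis_significance(rng.normal(size=(30, 5)), n_perm=49, random_state=1)
        assert np.all(p > 0) and np.all(p <= 1)

    def test_rejects_bad_n_perm(self):
        with pytest.raises(ValueError):
            axis_significance(np.zeros((10, 2)), n_perm=0)


def build_12_row_design():
    """Constructed 12-row dataset with group, sex and a size covariate."""
    rng = np.random.default_rng(8)
    data = pd.DataFrame(
        {
            "group": ["A", "A", "A", "B", "B", "B", "C", "C", "C", "D", "D", "D"],
            "sex": ["F", "M"] * 6,
            "size": np.round(rng.uniform(1.0, 2.0, 12), 3),
        }
    )
    y = (
        data["size"].to_numpy() * 0.5
        + data.groupby("group").ngroup().to_numpy() * 0.3
        + rng.normal(0, 0.2, 12)
    )
    return y, data


class TestProcrustesAnova:
    def test_univariate_matches_normal_equations_oracle(self):
        y, data = build_12_row_design()
        tbl = procrustes_anova(y, data, model_terms=("group", "sex", "size"),
                               n_perm=9, random_state=0)
        blocks = [
            pd.get_dummies(data["group"], drop_first=True).to_numpy(float),
            pd.get_dummies(data["sex"], drop_first=True).to_numpy(float),
            data["size"].to_numpy()[:, None],
        ]
        f_oracle = sequential_anova_oracle(y, blocks)
        np.testing.assert_allclose(tbl["F"].to_numpy()[:3], f_oracle, atol=1e-6)

    def test_constant_response_gives_zero_group_ss(self):
        data = pd.DataFrame({"group": ["A"] * 4 + ["B"] * 4})
        y = np.ones(8)
        tbl = procrustes_anova(y, data, model_terms=("group",), n_perm=9, random_state=0)
        assert tbl.loc[tbl["term"] == "group", "SS"].iloc[0] == pytest.approx(0, abs=1e-12)
        assert tbl.loc[tbl["term"] == "group", "F"].iloc[0] == pytest.approx(0, abs=1e-12)

    def test_ss_and_rsq_partition(self):
        y, data = build_12_row_design()
        rng = np.random.default_rng(9)
        Y = np.column_stack([y, y * 0.5 + rng.normal(0, 0.1, 12)])
        tbl = procrustes_anova(Y, data, model_terms=("group", "sex", "size"),
                               n_perm=19, random_state=0)
        terms = tbl[~tbl["term"].isin(["Total"])]
        total = tbl.loc[tbl["term"] == "Total", "SS"].iloc[0]
        assert terms["SS"].sum() == pytest.approx(total, abs=1e-8)
        assert terms["Rsq"].sum() == pytest.approx(1.0, abs=1e-8)
        assert terms["Df"].sum() == len(Y) - 1

    def test_rotation_invariance_of_stats(self):
        """Trace-based SS makes F and p invariant to rotating the response."""
        y, data = build_12_row_design()
        rng = np.random.default_rng(10)
        Y = np.column_stack([y, rng.normal(size=12), rng.normal(size=12)])
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t1 = procrustes_anova(Y, data, model_terms=("group", "size"), n_perm=99, random_state=5)
        t2 = procrustes_anova(Y @ Q, data, model_terms=("group", "size"), n_perm=99, random_state=5)
        np.testing.assert_allclose(t1["F"].dropna(), t2["F"].dropna(), atol=1e-8)
        np.testing.assert_allclose(t1["P"].dropna(), t2["P"].dropna(), atol=1e-12)

    def test_aliased_term_rejected(self):
        data = pd.DataFrame({"group": ["A", "A", "B", "B"] * 3,
                             "dup": ["A", "A", "B", "B"] * 3})
        y = np.arange(12.0)
        with pytest.raises(ValueError, match="aliased"):
            procrustes_anova(y, data, model_terms=("group", "dup"), n_perm=9)

    def test_estimator_interface(self):
        y, data = build_12_row_design()
        est = ProcrustesANOVA(model_terms=("group", "size"), n_perm=19, random_state=0)
        est.fit(y, data)
        assert set(est.anova_table_["term"]) >= {"group", "size", "Residuals", "Total"}
        assert est.set_params(n_perm=29).get_params()["n_perm"] == 29

    def test_null_permutation_p_uniform(self):
        """Under an exchangeable null the RRPP p-value is uniform (KS at
        alpha = 0.01 over 200 seeded replicates)."""
        rng = np.random.default_rng(11)
        data = pd.DataFrame({"group": ["A", "B", "C"] * 4})
        ps = []
        for _ in range(200):
            y = rng.normal(size=12)
            tbl = procrustes_anova(y, data, model_terms=("group",), n_perm=199,
                                   random_state=int(rng.integers(2**31)))
            ps.append(tbl["P"].iloc[0])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestPairwise:
    def test_identical_groups_distance_zero(self):
        rng = np.random.default_rng(12)
        block = rng.normal(size=(5, 3))
        Y = np.vstack([block, block])
        groups = ["A"] * 5 + ["B"] * 5
        (res,) = pairwise_groups(Y, groups, n_perm=99, random_state=0)
        assert res.statistic == pytest.approx(0, abs=1e-12)
        assert res.p_raw > 0.5

    def test_bonferroni_is_ten_times_raw_for_five_groups(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(25, 2))
        groups = [g for g in "ABCDE" for _ in range(5)]
        res = pairwise_groups(Y, groups, adjust="bonferroni", n_perm=99, random_state=1)
        assert len(res) == 10
        for r in res:
            assert r.p_adj == pytest.approx(min(1.0, 10 * r.p_raw))
            assert r.p_adj >= r.p_raw

    def test_displaced_group_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(14)
        Y = rng.normal(size=(50, 2), scale=0.3)
        groups = np.array([g for g in "ABCDE" for _ in range(10)])
        Y[groups == "E"] += [5.0, 0.0]
        res = pairwise_groups(Y, groups, n_perm=199, random_state=2)
        ranked = sorted(res, key=lambda r: r.p_adj)
        assert all("E" in r.pair for r in ranked[:4])

    def test_small_group_excluded(self):
        Y = np.arange(12, dtype=float)[:, None]
        groups = ["A"] * 5 + ["B"] * 6 + ["C"]
        res = pairwise_groups(Y, groups, n_perm=49, random_state=3)
        assert len(res) == 1 and res[0].pair == ("A", "B")
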