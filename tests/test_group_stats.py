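"""Univariate ANCOVA, post-hoc contrasts, admixture classification/regression."""

import numpy as np
import pandas as pd
import pytest

from cranioforge.datatypes import AdmixtureClass
from cranioforge.group_stats import (
    AncovaSpec,
    ancova,
    classify_admixture,
    hybrid_q_summary,
    posthoc_pairs,
    regress_on_admixture,
)
from cranioforge.shape_stats import procrustes_anova


class TestAncova:
    def test_two_group_hand_oracle(self):
        """One-way ANOVA on 6 rows: F computed by hand from group/residual SS."""
        df = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 6.0, 7.0, 8.0],
            "group": ["A", "A", "A", "B", "B", "B"],
        })
        fit = ancova(df, AncovaSpec(response="y", factors=("group",)))
        # group means 2 and 7, grand mean 4.5: SS_group = 6*2.5^2 = 37.5
        # residual SS = 4 (each group contributes 2), df = (1, 4) -> F = 37.5
        row = fit.table[fit.table["term"] == "group"].iloc[0]
        assert row["SS"] == pytest.approx(37.5, abs=1e-8)
        assert row["F"] == pytest.approx(37.5, abs=1e-8)

    def test_identical_rows_zero_f(self):
        df = pd.DataFrame({"y": [2.0] * 10, "group": ["A", "B"] * 5, "sex": ["F", "M"] * 5})
        fit = ancova(df, AncovaSpec(response="y"))
        assert fit.table[fit.table["term"] == "group"]["F"].iloc[0] == pytest.approx(0, abs=1e-8)

    def test_covariate_shift_leaves_group_f_unchanged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "y": rng.normal(size=24),
            "group": [g for g in "ABCD" for _ in range(6)],
            "sex": ["F", "M"] * 12,
            "size": rng.uniform(1, 2, 24),
        })
        spec = AncovaSpec(response="y", covariates=("size",))
        f1 = ancova(df, spec).table.set_index("term")["F"]
        df2 = df.assign(size=df["size"] + 100.0)
        f2 = ancova(df2, spec).table.set_index("term")["F"]
        np.testing.assert_allclose(f1.dropna(), f2.dropna(), atol=1e-8)

    def test_unknown_sex_excluded(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "y": rng.normal(size=12),
            "group": ["A", "B"] * 6,
            "sex": ["F", "M", "UNKNOWN"] * 4,
        })
        fit = ancova(df, AncovaSpec(response="y"))
        assert len(fit.data) == 8

    def test_matches_procrustes_anova_on_univariate_response(self):
        """Parametric sequential F values agree with the permutation module's
        trace-based decomposition on the same design."""
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "y": rng.normal(size=30),
            "group": [g for g in "ABCDE" for _ in range(6)],
            "sex": ["F", "M"] * 15,
            "size": rng.uniform(1, 2, 30),
        })
        fit = ancova(df, AncovaSpec(response="y", covariates=("size",)))
        tbl = procrustes_anova(df["y"].to_numpy(), df,
                               model_terms=("group", "sex", "size"), n_perm=9, random_state=0)
        f_param = fit.table.set_index("term")["F"]
        f_perm = tbl.set_index("term")["F"]
        for term in ("group", "sex", "size"):
            assert f_param[term] == pytest.approx(f_perm[term], abs=1e-6)


class TestPosthoc:
    def test_duplicated_groups_null(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=8)
        df = pd.DataFrame({
            "y": np.concatenate([base, base]),
            "group": ["A"] * 8 + ["B"] * 8,
            "sex": ["F", "M"] * 8,
        })
        fit = ancova(df, AncovaSpec(response="y"))
        (res,) = posthoc_pairs(fit)
        assert res.statistic == pytest.approx(0, abs=1e-10)
        assert res.p_raw > 0.99

    def test_holm_monotone_in_raw_p(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "y": rng.normal(size=40) + np.repeat([0, 0.5, 1.0, 3.0], 10),
            "group": [g for g in "ABCD" for _ in range(10)],
            "sex": ["F", "M"] * 20,
        })
        res = posthoc_pairs(ancova(df, AncovaSpec(response="y")))
        by_raw = sorted(res, key=lambda r: r.p_raw)
        adj = [r.p_adj for r in by_raw]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(r.p_adj >= r.p_raw for r in res)

    def test_shifted_group_power(self):
        """A 3-SD group shift at n = 12/group is detected in nearly every
        replicate (power simulation)."""
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            y = rng.normal(size=48)
            y[36:] += 3.0
            df = pd.DataFrame({"y": y, "group": [g for g in "ABCD" for _ in range(12)],
                               "sex": ["F", "M"] * 24})
            res = posthoc_pairs(ancova(df, AncovaSpec(response="y")))
            d_pairs = [r for r in res if "D" in r.pair]
            hits += all(r.p_adj < 0.05 for r in d_pairs)
        assert hits / n_rep >= 0.95


class TestAdmixture:
    @pytest.mark.parametrize("q,expected", [
        (0.90, AdmixtureClass.PURE_RED),
        (0.10, AdmixtureClass.PURE_DOUGLAS),
        (0.50, AdmixtureClass.HYBRID),
        (0.101, AdmixtureClass.HYBRID),
        (0.899, AdmixtureClass.HYBRID),
        (1.0, AdmixtureClass.PURE_RED),
        (0.0, AdmixtureClass.PURE_DOUGLAS),
    ])
    def test_threshold_boundaries(self, q, expected):
        assert classify_admixture(q) is expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_admixture(1.2)

    def test_exact_linear_trait(self):
        q = np.linspace(0.2, 0.8, 10)
        res = regress_on_admixture(2 * q + 1, q)
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_null_regression_r2_small(self):
        rng = np.random.default_rng(6)
        r2s, ps = [], []
        for _ in range(50):
            q = rng.uniform(0.15, 0.85, 19)
            y = rng.normal(size=19)
            res = regress_on_admixture(y, q)
            r2s.append(res.r2); ps.append(res.p)
        assert np.median(r2s) < 0.1
        # p roughly uniform: around half below 0.5
        assert 0.3 < np.mean(np.asarray(ps) < 0.5) < 0.7

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            regress_on_admixture([1.0, 2.0], [0.3, 0.4])

    def test_constant_q_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            regress_on_admixture([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])

    def test_hybrid_q_summary_fields(self):
        rng = np.random.default_rng(7)
        s = hybrid_q_summary(rng.uniform(0.2, 0.8, 19))
        assert s["n"] == 19
        assert 0.2 <= s["mean_q"] <= 0.8
        assert s["ci95_halfwidth"] > 0
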