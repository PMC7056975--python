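"""ANOVA engine: closed-form checks, EMS denominators, statsmodels
cross-validation, Tukey oracle, and structural invariants."""

import numpy as np
import pandas as pd
import pytest

from senescan import AnovaModel, parse_formula
from senescan.anova import AliasedTermError, FormulaError, Term
from oracles import balanced_two_way_ss, nested_mixed_f, pooled_t_squared, tukey_q_matrix


def two_way_frame(y):
    a, b, n = y.shape
    rows = []
    for i in range(a):
        for j in range(b):
            for k in range(n):
                rows.append((f"a{i}", f"b{j}", y[i, j, k]))
    return pd.DataFrame(rows, columns=["A", "B", "y"])


class TestFormulaParsing:
    def test_terms_and_nesting(self):
        resp, terms = parse_formula("lifespan ~ S + G + S*G + Rep(G) + S*Rep(G)")
        assert resp == "lifespan"
        assert terms == [
            Term(("S",)),
            Term(("G",)),
            Term(("S", "G")),
            Term((), ("G",)),
            Term(("S",), ("G",)),
        ]
        assert [t.is_random for t in terms] == [False, False, False, True, True]

    def test_rep_nest_accepts_star_or_comma(self):
        _, t1 = parse_formula("y ~ L + G + L*G + Rep(L*G)")
        _, t2 = parse_formula("y ~ L + G + L*G + Rep(L,G)")
        assert t1 == t2

    def test_interaction_without_parent_rejected(self):
        with pytest.raises(FormulaError, match="main effect"):
            parse_formula("y ~ A + A*B")

    def test_bare_rep_rejected(self):
        with pytest.raises(FormulaError, match="nested"):
            parse_formula("y ~ G + Rep")


class TestClosedForms:
    def test_balanced_two_way_matches_cell_mean_formulas(self, rng):
        y = rng.normal(size=(2, 2, 5)) + np.array([[0, 1], [2, 4]])[:, :, None]
        expected = balanced_two_way_ss(y)
        res = AnovaModel.from_formula("y ~ A + B + A*B", two_way_frame(y)).fit()
        t = res.anova_table
        for term in ("A", "B", "A*B", "Residual"):
            assert t.loc[term, "sum_sq"] == pytest.approx(expected[term], rel=1e-10)

    def test_two_level_factor_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        df = pd.DataFrame({"G": ["x"] * 12 + ["y"] * 12, "y": np.concatenate([a, b])})
        res = AnovaModel.from_formula("y ~ G", df).fit()
        t2, p = pooled_t_squared(a, b)
        assert res.anova_table.loc["G", "F"] == pytest.approx(t2, rel=1e-10)
        assert res.anova_table.loc["G", "p"] == pytest.approx(p, rel=1e-10)

    def test_identical_genotypes_give_zero_f_and_p_one(self):
        # two genotypes with the same values in each of 2 vials
        rows = []
        for g in ("g1", "g2"):
            for v, vals in (("v1", (10, 12)), ("v2", (10, 12))):
                rows += [(g, f"{g}_{v}", x) for x in vals]
        df = pd.DataFrame(rows, columns=["G", "vial", "y"])
        res = AnovaModel.from_formula("y ~ G + Rep(G)", df, rep_col="vial").fit()
        assert res.anova_table.loc["G", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert res.anova_table.loc["G", "F"] == pytest.approx(0.0, abs=1e-9)
        assert res.anova_table.loc["G", "p"] == pytest.approx(1.0)


class TestMixedModelEMS:
    def build(self, rng, g=2, v=6, s=2, n=3):
        y = (
            rng.normal(size=(g, v, s, n))
            + np.arange(g)[:, None, None, None] * 1.5
            + rng.normal(0, 2, size=(g, v))[:, :, None, None]  # vial effects
        )
        rows = []
        for gi in range(g):
            for vi in range(v):
                for si in range(s):
                    for ni in range(n):
                        rows.append((f"g{gi}", "FM"[si], f"g{gi}_v{vi}", y[gi, vi, si, ni]))
        return y, pd.DataFrame(rows, columns=["G", "S", "vial", "y"])

    def test_denominators_follow_expected_mean_squares(self, rng):
        _, df = self.build(rng)
        res = AnovaModel.from_formula("y ~ S + G + S*G + Rep(G) + S*Rep(G)", df, rep_col="vial").fit()
        denom = res.anova_table["denom"]
        assert denom["G"] == "Rep(G)"
        assert denom["S"] == "S*Rep(G)"
        assert denom["S*G"] == "S*Rep(G)"
        assert denom["Rep(G)"] == "S*Rep(G)"
        assert denom["S*Rep(G)"] == "Residual"

    def test_balanced_mixed_f_matches_hand_computation(self, rng):
        y, df = self.build(rng)
        res = AnovaModel.from_formula("y ~ S + G + S*G + Rep(G) + S*Rep(G)", df, rep_col="vial").fit()
        expected = nested_mixed_f(y)
        for term, f_exp in expected["F"].items():
            assert res.anova_table.loc[term, "F"] == pytest.approx(f_exp, rel=1e-8), term

    def test_balanced_decomposition_is_orthogonal(self, rng):
        _, df = self.build(rng, g=3, v=4)
        res = AnovaModel.from_formula("y ~ S + G + S*G + Rep(G) + S*Rep(G)", df, rep_col="vial").fit()
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert res.anova_table["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_row_permutation_invariance(self, rng):
        _, df = self.build(rng)
        f = "y ~ S + G + S*G + Rep(G) + S*Rep(G)"
        t1 = AnovaModel.from_formula(f, df, rep_col="vial").fit().anova_table
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        t2 = AnovaModel.from_formula(f, shuffled, rep_col="vial").fit().anova_table
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index(), rtol=1e-9)


def test_unbalanced_fixed_matches_statsmodels_type3(rng):
    """Partial SS on unbalanced data agrees with the independent Type-III
    computation (sum-to-zero contrasts)."""
    smf = pytest.importorskip("statsmodels.formula.api")
    from statsmodels.stats.anova import anova_lm

    y = rng.normal(size=(2, 3, 6)) + np.arange(3)[None, :, None]
    df = two_way_frame(y).sample(frac=0.8, random_state=3).reset_index(drop=True)  # unbalance
    res = AnovaModel.from_formula("y ~ A + B + A*B", df).fit()
    ols = smf.ols("y ~ C(A, Sum) * C(B, Sum)", df).fit()
    sm_tab = anova_lm(ols, typ=3)
    for term, sm_term in [("A", "C(A, Sum)"), ("B", "C(B, Sum)"), ("A*B", "C(A, Sum):C(B, Sum)")]:
        assert res.anova_table.loc[term, "sum_sq"] == pytest.approx(sm_tab.loc[sm_term, "sum_sq"], rel=1e-8)
        assert res.anova_table.loc[term, "F"] == pytest.approx(sm_tab.loc[sm_term, "F"], rel=1e-8)


class TestTukey:
    def frame(self, means, n=6, sd=0.01, seed=5):
        rng = np.random.default_rng(seed)
        rows = []
        for i, m in enumerate(means):
            for x in rng.normal(m, sd, size=n):
                rows.append((f"g{i}", x))
        return pd.DataFrame(rows, columns=["G", "y"])

    def test_two_separated_groups_get_distinct_letters(self):
        res = AnovaModel.from_formula("y ~ G", self.frame([50, 5])).fit()
        tk = res.tukey("G")
        assert tk.letters == {"g0": "a", "g1": "b"}

    def test_identical_groups_share_a_letter(self):
        df = self.frame([10, 10, 10], sd=1.0)
        tk = AnovaModel.from_formula("y ~ G", df).fit().tukey("G")
        assert set(tk.letters.values()) == {"a"}

    def test_q_statistics_match_direct_oracle(self, rng):
        df = self.frame([3, 5, 5.5, 9], n=5, sd=1.2, seed=9)
        res = AnovaModel.from_formula("y ~ G", df).fit()
        tk = res.tukey("G")
        cm = res.cell_means("G").set_index("G")
        q_exp = tukey_q_matrix(
            cm["mean"].to_numpy(), cm["n"].to_numpy(), res.anova_table.loc["Residual", "mean_sq"]
        )
        labels = list(cm.index)
        for row in tk.table.itertuples(index=False):
            i, j = labels.index(row.level_a), labels.index(row.level_b)
            assert row.q == pytest.approx(q_exp[i, j], rel=1e-10)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"G": ["a"] * 4, "H": ["x", "x", "y", "y"], "y": [1.0, 2, 3, 4]})
        res = AnovaModel.from_formula("y ~ H", df).fit()
        with pytest.raises(ValueError):
            res.tukey("G")


class TestErrors:
    def test_aliased_term_named(self):
        df = pd.DataFrame({"A": ["a", "a", "b", "b"], "B": ["x", "x", "y", "y"], "y": [1.0, 2, 3, 4]})
        with pytest.raises(AliasedTermError, match="aliased"):
            AnovaModel.from_formula("y ~ A + B", df).fit()

    def test_zero_residual_df(self):
        df = pd.DataFrame({"A": ["a", "b"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="residual"):
            AnovaModel.from_formula("y ~ A", df).fit()

    def test_single_level_factor(self):
        df = pd.DataFrame({"A": ["a"] * 4, "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="fewer than 2"):
            AnovaModel.from_formula("y ~ A", df).fit()

    def test_empty_cell_in_interaction(self):
        df = pd.DataFrame(
            {"A": ["a", "a", "b", "b", "a", "b"], "B": ["x", "x", "x", "x", "y", "x"], "y": np.arange(6.0)}
        )
        with pytest.raises(ValueError, match="empty cell"):
            AnovaModel.from_formula("y ~ A + B + A*B", df).fit()


def test_summary_contains_table_and_formula(rng):
    df = pd.DataFrame({"G": ["a"] * 5 + ["b"] * 5, "y": rng.normal(size=10)})
    s = AnovaModel.from_formula("y ~ G", df).fit().summary()
    assert "y ~ G" in s and "Residual" in s and "sum_sq" in s
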