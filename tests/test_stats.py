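"""Welch t, Wilcoxon signed-rank, factorial ANOVA, and Tukey HSD."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from drwhite import (
    FactorialDesign,
    TraceSimParams,
    calls_to_frame,
    classify_spectrum,
    decompose,
    factorial_anova,
    format_p,
    melt_pathway,
    simulate_cohort,
    tukey_hsd,
    welch_t_test,
    wilcoxon_signed_rank,
)
from drwhite.profiles import TRACE_PROFILES


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_closed_form_and_scipy(self):
        x = np.array([1.0, 2.0, 3.0])
        y = x + 10.0
        t, df, p = welch_t_test(x, y)
        # hand formula: vx = vy = 1, se^2 = 2/3, Satterthwaite df = 4
        assert t == pytest.approx(-10.0 / np.sqrt(2.0 / 3.0))
        assert df == pytest.approx(4.0)
        ref = scipy.stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 10)
        t1, _, p1 = welch_t_test(x, y)
        t2, _, p2 = welch_t_test(3.0 * x + 7.0, 3.0 * y + 7.0)
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        t, _, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0
        with pytest.warns(RuntimeWarning, match="zero variance"):
            t, _, p = welch_t_test([2.0, 2.0], [5.0, 5.0])
        assert p == 0.0 and np.isinf(t)


def _exact_wilcoxon_p(x, y):
    """Enumeration oracle: all 2^n sign assignments of the rank sum."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.array(dist)
    p = 2.0 * min((dist <= w_obs).mean(), (dist >= w_obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_identical_pairs_give_p1(self):
        with pytest.warns(RuntimeWarning, match="zero"):
            w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_small_n_matches_enumeration_oracle(self):
        x = np.array([10.0, 8.0, 6.0, 4.0, 2.0])
        y = np.array([9.0, 10.5, 2.0, 9.5, 1.0])
        w, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(_exact_wilcoxon_p(x, y))
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(0, 1, 6)
            b = a + rng.normal(0.3, 1, 6)
            _, p = wilcoxon_signed_rank(a, b)
            assert p == pytest.approx(_exact_wilcoxon_p(a, b))

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 1, 9)
        _, p_xy = wilcoxon_signed_rank(x, y)
        _, p_yx = wilcoxon_signed_rank(y, x)
        assert p_xy == pytest.approx(p_yx)


def _balanced_toy(seed=0, effect_a=2.0, effect_b=-1.0, interaction=0.5, n=3):
    rng = np.random.default_rng(seed)
    rows = []
    for a in (0, 1):
        for b in (0, 1):
            mu = 10 + effect_a * a + effect_b * b + interaction * a * b
            for _ in range(n):
                rows.append(
                    {"a": f"a{a}", "b": f"b{b}", "y": mu + rng.normal(0, 1)}
                )
    return pd.DataFrame(rows)


def _explicit_two_way_f(df):
    """Sums-of-squares oracle for a balanced 2x2 design."""
    grand = df["y"].mean()
    n_cell = df.groupby(["a", "b"]).size().iloc[0]
    ss_a = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("a")
    )
    ss_b = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("b")
    )
    cell_means = df.groupby(["a", "b"])["y"].mean()
    a_means = df.groupby("a")["y"].mean()
    b_means = df.groupby("b")["y"].mean()
    ss_ab = n_cell * sum(
        (cell_means[a, b] - a_means[a] - b_means[b] + grand) ** 2
        for a, b in cell_means.index
    )
    ss_err = sum(
        ((g["y"] - g["y"].mean()) ** 2).sum() for _, g in df.groupby(["a", "b"])
    )
    df_err = len(df) - 4
    mse = ss_err / df_err
    return {"a": ss_a / 1 / mse, "b": ss_b / 1 / mse, "a:b": ss_ab / 1 / mse}


class TestFactorialAnova:
    def test_balanced_two_way_matches_explicit_sums_of_squares(self):
        data = _balanced_toy()
        res = factorial_anova(FactorialDesign("y", ("a", "b"), data))
        expected = _explicit_two_way_f(data)
        table = res.table.set_index("effect")
        for effect, f in expected.items():
            assert table.loc[effect, "F"] == pytest.approx(f)
        assert res.ss_type == "sequential"
        assert table["df2"].eq(len(data) - 4).all()

    def test_constant_shift_leaves_f_unchanged(self):
        data = _balanced_toy(seed=1)
        shifted = data.assign(y=data["y"] + 100.0)
        f1 = factorial_anova(FactorialDesign("y", ("a", "b"), data)).table["F"]
        f2 = factorial_anova(FactorialDesign("y", ("a", "b"), shifted)).table["F"]
        assert f1.to_numpy() == pytest.approx(f2.to_numpy())

    def test_unbalanced_design_uses_marginal_ss(self):
        data = _balanced_toy(seed=2)
        data = pd.concat([data, data.iloc[[0, 1]]], ignore_index=True)
        res = factorial_anova(FactorialDesign("y", ("a", "b"), data))
        assert res.ss_type == "marginal"
        assert np.isfinite(res.table["F"]).all()

    def test_null_permutations_give_f_near_one(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 20)
        fs = []
        for _ in range(200):
            labels_a = rng.permutation(["a0"] * 10 + ["a1"] * 10)
            labels_b = rng.permutation(["b0"] * 10 + ["b1"] * 10)
            data = pd.DataFrame({"y": y, "a": labels_a, "b": labels_b})
            try:
                res = factorial_anova(FactorialDesign("y", ("a", "b"), data))
            except ValueError:  # a permutation left an empty cell
                continue
            fs.append(res.table.set_index("effect").loc["a", "F"])
        assert 0.7 < np.mean(fs) < 1.5

    def test_single_level_factor_rejected(self):
        data = _balanced_toy().assign(a="a0")
        with pytest.raises(ValueError, match="fewer than 2"):
            FactorialDesign("y", ("a", "b"), data)

    def test_saturated_design_flags_untestable_interaction(self):
        data = _balanced_toy(n=1)
        with pytest.warns(RuntimeWarning, match="saturated"):
            res = factorial_anova(FactorialDesign("y", ("a", "b"), data))
        assert not res.interaction_testable


class TestTukey:
    def _one_way(self, means, n=5, seed=6):
        rng = np.random.default_rng(seed)
        rows = []
        for i, mu in enumerate(means):
            for _ in range(n):
                rows.append({"g": f"g{i}", "y": mu + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_equal_group_values_give_p1(self):
        data = pd.DataFrame(
            {"g": ["g0"] * 3 + ["g1"] * 3, "y": [1.0, 2.0, 3.0] * 2}
        )
        design = FactorialDesign("y", ("g",), data)
        out = tukey_hsd(design)
        assert out["q"].to_numpy() == pytest.approx(0.0)
        assert out["p_adj"].to_numpy() == pytest.approx(1.0)

    def test_three_groups_match_statsmodels_cross_check(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = self._one_way([0.0, 1.5, 4.0])
        design = FactorialDesign("y", ("g",), data)
        ours = tukey_hsd(design)
        sm_res = pairwise_tukeyhsd(data["y"], data["g"])
        np.testing.assert_allclose(ours["diff"], sm_res.meandiffs, atol=1e-10)
        np.testing.assert_allclose(ours["p_adj"], sm_res.pvalues, atol=1e-8)
        np.testing.assert_allclose(
            ours[["ci_lower", "ci_upper"]], sm_res.confint, atol=1e-8
        )

    def test_adjusted_p_dominates_unadjusted_pairwise(self):
        data = self._one_way([0.0, 0.8, 1.6, 2.0], seed=7)
        design = FactorialDesign("y", ("g",), data)
        res = factorial_anova(design)
        out = tukey_hsd(design, anova=res)
        counts = data.groupby("g").size()
        for row in out.itertuples():
            se_t = np.sqrt(res.mse * (1 / counts[row.group1] + 1 / counts[row.group2]))
            p_unadj = 2 * scipy.stats.t.sf(abs(row.diff) / se_t, res.df_resid)
            assert row.p_adj >= p_unadj - 1e-12

    def test_single_group_gives_empty_table(self):
        data = self._one_way([0.0, 1.0]).assign(batch="b0")
        design = FactorialDesign("y", ("g",), data)
        anova = factorial_anova(design)
        assert len(tukey_hsd(design, effect="g", anova=anova)) == 1
        assert tukey_hsd(design, effect="batch", anova=anova).empty


def test_three_way_reproduction_layout_separates_stage_not_sex(ref):
    """Complementary HR/NHEJ rows: strong stage-by-pathway interaction,
    non-significant sex term, mirroring the brain-tissue comparison.

    The preset truths encode small sex differences (e.g. adult head 28.1
    vs 25.7% HR), so the sex-by-pathway contrast is not asserted to be
    null; the sex term itself must be."""
    cohorts = {
        ("larva", "male"): ("larval_brain_male", 23),
        ("adult", "male"): ("adult_head_male", 38),
        ("larva", "female"): ("larval_brain_female", 25),
        ("adult", "female"): ("adult_head_female", 38),
    }
    calls = []
    seed = 10
    for (stage, sex), (label, n) in cohorts.items():
        profile = TRACE_PROFILES[label]
        for sim in simulate_cohort(profile, n, TraceSimParams(seed=seed), ref=ref):
            call = classify_spectrum(
                decompose(sim.control, sim.sample, ref),
                -23,
                sample_id=sim.sample_id,
                sex=sex,
                tissue=stage,
            )
            calls.append(call)
        seed += 1
    long = melt_pathway(calls_to_frame(calls))
    long = long.rename(columns={"tissue": "stage"})
    design = FactorialDesign("value", ("stage", "sex", "pathway"), long)
    res = factorial_anova(design)
    table = res.table.set_index("effect")
    assert table.loc["stage:pathway", "F"] > 100
    assert table.loc["stage:pathway", "p"] < 1e-10
    assert table.loc["sex", "p"] > 0.05
    assert res.df_resid == 2 * (23 + 38 + 25 + 38) - 8


def test_p_value_floor_formatting():
    assert format_p(1e-20) == "< 1e-15"
    assert format_p(0.0321).startswith("0.0321")
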