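"""t tests, repeated-measures ANOVA, Tukey HSD — against hand and library oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sst

import optopav as op


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        res = op.one_sample_t([1.0, -1.0, 2.0, -2.0], mu0=0.0)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_df_for_four_subjects(self):
        assert op.one_sample_t([0.1, 0.2, 0.3, 0.4]).df == 3.0

    def test_hand_computed_toy(self):
        # {1,2,3,4}: mean 2.5, sd 1.29099..., t = 2.5 / (sd / 2)
        res = op.one_sample_t([1, 2, 3, 4], mu0=0.0)
        sd = np.std([1, 2, 3, 4], ddof=1)
        assert res.statistic == pytest.approx(2.5 / (sd / 2.0), rel=1e-12)
        ref = sst.ttest_1samp([1, 2, 3, 4], 0.0)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_flagged_infinite(self):
        res = op.one_sample_t([2.0, 2.0, 2.0], mu0=0.0)
        assert res.degenerate and np.isinf(res.statistic)
        on_target = op.one_sample_t([2.0, 2.0, 2.0], mu0=2.0)
        assert on_target.degenerate and on_target.statistic == 0.0


class TestTwoSampleT:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert op.unpaired_t(g, list(g)).statistic == 0.0
        assert op.unpaired_t(g, list(g)).df == 6.0

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        res = op.unpaired_t(a, b)
        ref = sst.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=5)
        b = a + rng.normal(0.3, 0.2, size=5)
        res = op.paired_t(a, b)
        ref = sst.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.df == 4.0

    def test_constant_nonzero_difference_flagged(self):
        res = op.paired_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        assert res.degenerate and np.isinf(res.statistic)


class TestTwoWayRmAnova:
    def _tidy(self, x):
        n, a, b = x.shape
        rows = [{"subject": f"m{i}", "session": j + 1,
                 "trial_type": f"c{k}", "value": x[i, j, k]}
                for i in range(n) for j in range(a) for k in range(b)]
        return pd.DataFrame(rows)

    def test_df_structure_four_subjects_ten_sessions(self):
        rng = np.random.default_rng(3)
        res = op.two_way_rm_anova(rng.normal(size=(4, 10, 2)))
        eff = res.effects.set_index("effect")
        assert (eff.loc["session", "df1"], eff.loc["session", "df2"]) == (9, 27)
        assert (eff.loc["trial_type", "df1"], eff.loc["trial_type", "df2"]) == (1, 3)
        assert (eff.loc["interaction", "df1"], eff.loc["interaction", "df2"]) == (9, 27)

    def test_all_cells_equal_gives_zero_f(self):
        res = op.two_way_rm_anova(np.full((4, 10, 2), 3.7))
        assert np.allclose(res.effects["F"], 0.0)
        assert np.allclose(res.effects["p"], 1.0)

    def test_hand_decomposition_2x2x3(self):
        """SS decomposition vs an explicit loop computation on a small table."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 2, 2)) + np.arange(2)[None, :, None] * 0.5
        n, a, b = x.shape
        g = x.mean()
        # independent oracle: textbook mean decomposition with explicit loops
        ss_a = sum(n * b * (x[:, j, :].mean() - g) ** 2 for j in range(a))
        ss_ab = sum(n * (x[:, j, k].mean() - x[:, j, :].mean()
                         - x[:, :, k].mean() + g) ** 2
                    for j in range(a) for k in range(b))
        ss_as = sum(b * (x[i, j, :].mean() - x[:, j, :].mean()
                         - x[i].mean() + g) ** 2
                    for i in range(n) for j in range(a))
        f_a_ref = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
        res = op.two_way_rm_anova(x)
        eff = res.effects.set_index("effect")
        assert eff.loc["session", "F"] == pytest.approx(f_a_ref, rel=1e-10)
        assert eff.loc["interaction", "df1"] == (a - 1) * (b - 1)
        assert ss_ab >= 0

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 10, 2))
        x += np.arange(10)[None, :, None] * 0.1  # a session effect
        tidy = self._tidy(x)
        res = op.two_way_rm_anova(tidy, factor_a="session", factor_b="trial_type")
        ref = AnovaRM(tidy, depvar="value", subject="subject",
                      within=["session", "trial_type"]).fit().anova_table
        eff = res.effects.set_index("effect")
        assert eff.loc["session", "F"] == pytest.approx(
            ref.loc["session", "F Value"], rel=1e-8)
        assert eff.loc["trial_type", "F"] == pytest.approx(
            ref.loc["trial_type", "F Value"], rel=1e-8)
        assert eff.loc["interaction", "F"] == pytest.approx(
            ref.loc["session:trial_type", "F Value"], rel=1e-8)
        assert res.p_value == pytest.approx(
            ref.loc["session:trial_type", "Pr > F"], rel=1e-8)

    def test_missing_cell_fails(self):
        tidy = self._tidy(np.random.default_rng(6).normal(size=(3, 4, 2)))
        with pytest.raises(op.StatsError):
            op.two_way_rm_anova(tidy.iloc[:-1], factor_a="session",
                                factor_b="trial_type")


class TestOneWayRmAnova:
    def test_identical_conditions(self):
        x = np.tile([[1.0], [2.0], [3.0]], (1, 4))  # subjects differ, conditions equal
        res = op.one_way_rm_anova(x)
        assert res.statistic == 0.0
        post = op.tukey_posthoc(pd.DataFrame(x))
        assert np.allclose(post["p_value"], 1.0)

    def test_df_structure_matches_small_cohorts(self):
        rng = np.random.default_rng(7)
        assert op.one_way_rm_anova(rng.normal(size=(3, 4))).df == (3.0, 6.0)
        assert op.one_way_rm_anova(rng.normal(size=(4, 3))).df == (2.0, 6.0)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(8)
        x = rng.normal(size=(5, 3)) + np.array([0.0, 0.3, 0.0])
        tidy = pd.DataFrame([{"subject": i, "condition": j, "value": x[i, j]}
                             for i in range(5) for j in range(3)])
        res = op.one_way_rm_anova(
            tidy.rename(columns={"value": "auc"}))
        ref = AnovaRM(tidy, depvar="value", subject="subject",
                      within=["condition"]).fit().anova_table
        assert res.statistic == pytest.approx(ref.loc["condition", "F Value"],
                                              rel=1e-8)
        assert res.p_value == pytest.approx(ref.loc["condition", "Pr > F"],
                                            rel=1e-8)

    def test_tukey_flags_exactly_the_shifted_group(self):
        """Tukey vs all-pairs Bonferroni paired-t as a conservative oracle."""
        rng = np.random.default_rng(9)
        n = 6
        base = rng.normal(0, 0.05, size=n)
        x = np.column_stack([base + rng.normal(0, 0.05, n),
                             base + rng.normal(0, 0.05, n),
                             base + 2.0 + rng.normal(0, 0.05, n)])
        table = pd.DataFrame(x, columns=["A", "B", "C"])
        post = op.tukey_posthoc(table).set_index(["group_a", "group_b"])
        assert not post.loc[("A", "B"), "significant"]
        assert post.loc[("A", "C"), "significant"]
        assert post.loc[("B", "C"), "significant"]
        # Bonferroni-corrected paired t flags the same pairs
        pairs = {("A", "B"): (0, 1), ("A", "C"): (0, 2), ("B", "C"): (1, 2)}
        for pair, (i, j) in pairs.items():
            p_bonf = min(1.0, 3 * sst.ttest_rel(x[:, i], x[:, j]).pvalue)
            assert (p_bonf < 0.05) == bool(post.loc[pair, "significant"])


class TestCrossConsistency:
    def test_paired_t_squared_equals_two_condition_rm_f(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(6, 2)) + np.array([0.0, 0.4])
        t = op.paired_t(x[:, 0], x[:, 1]).statistic
        f = op.one_way_rm_anova(x).statistic
        assert t ** 2 == pytest.approx(f, rel=1e-8)

    def test_unpaired_t_squared_equals_oneway_f(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 7), rng.normal(0.6, 1, 7)
        t = op.unpaired_t(a, b).statistic
        f = sst.f_oneway(a, b).statistic
        assert t ** 2 == pytest.approx(f, rel=1e-8)
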