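"""Outlier screening, effect sizes, t-tests, balanced ANOVA, permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from pavca.stats import (
    balanced_two_way_anova,
    bonferroni,
    cohens_d,
    interaction_permutation_test,
    iqr_outliers,
    two_sample_t,
)


class TestIqrOutliers:
    def test_manual_quartile_oracle(self):
        # sorted {1,2,3,4,100}: Q1=2, Q3=4 by linear interpolation,
        # bounds [2-3, 4+3] = [-1, 7] -> only 100 removed
        rep = iqr_outliers([1, 2, 3, 4, 100])
        assert rep.q1 == 2.0 and rep.q3 == 4.0
        assert rep.bounds == (-1.0, 7.0)
        assert list(rep.removed) == [100.0]
        assert sorted(rep.kept) == [1, 2, 3, 4]

    def test_all_equal_values_nothing_removed(self):
        rep = iqr_outliers([5.0] * 8)
        assert rep.iqr == 0.0
        assert rep.removed.size == 0

    def test_symmetric_data_without_extremes(self, rng):
        rep = iqr_outliers(np.linspace(-1, 1, 20))
        assert rep.removed.size == 0

    def test_small_sample_skipped_with_warning(self):
        rep = iqr_outliers([1.0, 2.0, 300.0])
        assert rep.removed.size == 0
        assert rep.warning is not None

    @given(
        hst.lists(hst.floats(-100, 100), min_size=5, max_size=40),
        hst.floats(-50, 50),
        hst.floats(0.1, 10),
    )
    def test_shift_invariant_and_scale_equivariant(self, values, shift, scale):
        base = iqr_outliers(values)
        shifted = iqr_outliers([v + shift for v in values])
        scaled = iqr_outliers([v * scale for v in values])
        assert shifted.removed.size == base.removed.size
        assert scaled.removed.size == base.removed.size
        assert np.allclose(sorted(shifted.removed), sorted(np.asarray(base.removed) + shift))
        assert np.allclose(sorted(scaled.removed), sorted(np.sort(base.removed) * scale))


class TestCohensD:
    def test_unit_separation(self, rng):
        x = rng.normal(1, 1, 100_000)
        y = rng.normal(0, 1, 100_000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.02)

    def test_identical_groups_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert cohens_d(g, g) == 0.0

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(0, 2, 12)
        y = rng.normal(1, 3, 20)
        sp = np.sqrt(
            ((len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1))
            / (len(x) + len(y) - 2)
        )
        assert cohens_d(x, y) == pytest.approx((np.mean(x) - np.mean(y)) / sp)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1.5, 10)
        assert cohens_d(x, y) == pytest.approx(
            pingouin.compute_effsize(x, y, eftype="cohen")
        )

    @given(
        hst.lists(hst.floats(-10, 10), min_size=2, max_size=20),
        hst.lists(hst.floats(-10, 10), min_size=2, max_size=20),
    )
    def test_antisymmetric(self, x, y):
        try:
            d = cohens_d(x, y)
        except ValueError:
            return  # zero pooled SD
        assert d == pytest.approx(-cohens_d(y, x))


class TestTwoSampleT:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = two_sample_t(g, list(g))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_identity_two_pooled_sds_apart(self):
        """|t| = d * sqrt(n^2 / 2n) when groups of equal n differ by d pooled SDs."""
        g1 = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        sd = g1.std(ddof=1)
        g2 = g1 + 2 * sd
        res = two_sample_t(g2, g1)
        assert res.effect_size_d == pytest.approx(2.0)
        assert res.statistic == pytest.approx(2 * np.sqrt(25 / 10))
        assert res.statistic == pytest.approx(3.162, abs=1e-3)

    def test_df_rule(self):
        res = two_sample_t([1.0, 2, 3, 4, 5], [2.0, 3, 4, 5, 7])
        assert res.df == 8

    def test_paired_df(self):
        res = two_sample_t([1.0, 2, 3, 4], [2.0, 3, 5, 4], paired=True)
        assert res.df == 3

    def test_paired_requires_equal_n(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 2, 3], [1.0, 2], paired=True)


def did_table(n_per_arm, effect, rng, sd=1.0):
    rows = []
    for arm, shift in (("VEH", 0.0), ("CNO", effect)):
        for i in range(n_per_arm):
            rat = f"{arm}{i}"
            b1 = rng.normal(0, sd)
            rows.append({"rat_id": rat, "block": "rescreen", "treatment": arm, "value": b1})
            rows.append(
                {"rat_id": rat, "block": "test", "treatment": arm, "value": b1 + shift + rng.normal(0, sd)}
            )
    return pd.DataFrame(rows)


class TestInteractionPermutation:
    def test_constructed_gain_recovered_exactly(self):
        rows = []
        for arm, gain in (("VEH", 0.0), ("CNO", 0.7)):
            for i in range(4):
                base = 0.1 * i
                rows.append({"rat_id": f"{arm}{i}", "block": "b1", "treatment": arm, "value": base})
                rows.append({"rat_id": f"{arm}{i}", "block": "b2", "treatment": arm, "value": base + gain})
        res = interaction_permutation_test(
            pd.DataFrame(rows), n_perm=99, seed=1, treated="CNO"
        )
        assert res["observed"] == pytest.approx(0.7)

    def test_detects_large_effect(self, rng):
        table = did_table(8, effect=3.0, rng=rng, sd=0.5)
        res = interaction_permutation_test(table, n_perm=999, seed=0)
        assert res["p"] < 0.01

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            interaction_permutation_test(did_table(4, 0.0, rng), n_perm=0)

    def test_too_few_rats_rejected(self, rng):
        table = did_table(1, 0.0, rng)
        with pytest.raises(ValueError, match="2 rats"):
            interaction_permutation_test(table, n_perm=9)

    def test_p_in_unit_interval_and_deterministic(self, rng):
        table = did_table(5, effect=0.5, rng=rng)
        res1 = interaction_permutation_test(table, n_perm=199, seed=42)
        res2 = interaction_permutation_test(table, n_perm=199, seed=42)
        assert 0 < res1["p"] <= 1
        assert res1 == res2


class TestBalancedAnova:
    @staticmethod
    def table(rng, a_eff=0.0, b_eff=0.0, ab_eff=0.0, r=5, sd=1.0):
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                mu = a_eff * a + b_eff * b + ab_eff * a * b
                for _ in range(r):
                    rows.append({"A": f"a{a}", "B": f"b{b}", "value": mu + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_flat_cells_give_zero_f(self, rng):
        t = self.table(rng, sd=1.0)
        t["value"] = 1.0
        res = balanced_two_way_anova(t, "A", "B")
        assert res.loc["A", "ss"] == pytest.approx(0.0)
        assert res.loc["A:B", "ss"] == pytest.approx(0.0)

    def test_additive_effects_no_interaction(self, rng):
        t = self.table(rng, a_eff=2.0, b_eff=1.0, sd=0.0)
        # noise-free additive design: interaction SS identically 0
        t["value"] += rng.normal(0, 1e-9, len(t))
        res = balanced_two_way_anova(t, "A", "B")
        assert res.loc["A:B", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["A", "F"] > 1e6

    def test_ss_conservation(self, rng):
        t = self.table(rng, a_eff=1.0, b_eff=-0.5, ab_eff=0.8)
        res = balanced_two_way_anova(t, "A", "B")
        parts = res.loc[["A", "B", "A:B", "error"], "ss"].sum()
        assert parts == pytest.approx(res.loc["total", "ss"], rel=1e-12)

    def test_matches_statsmodels(self, rng):
        sm_api = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols

        t = self.table(rng, a_eff=1.0, b_eff=0.5, ab_eff=-0.7, r=4)
        res = balanced_two_way_anova(t, "A", "B")
        fit = ols("value ~ C(A) * C(B)", data=t).fit()
        sm_tab = sm_api.stats.anova_lm(fit, typ=2)
        assert res.loc["A", "F"] == pytest.approx(sm_tab.loc["C(A)", "F"])
        assert res.loc["B", "F"] == pytest.approx(sm_tab.loc["C(B)", "F"])
        assert res.loc["A:B", "F"] == pytest.approx(sm_tab.loc["C(A):C(B)", "F"])
        assert res.loc["A:B", "p"] == pytest.approx(sm_tab.loc["C(A):C(B)", "PR(>F)"])

    def test_unbalanced_rejected(self, rng):
        t = self.table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            balanced_two_way_anova(t, "A", "B")


def test_bonferroni_caps_at_one():
    out = bonferroni([0.01, 0.4, 0.04], alpha=0.05)
    assert np.allclose(out["p_adj"], [0.03, 1.0, 0.12])
    assert list(out["reject"]) == [True, False, False]
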