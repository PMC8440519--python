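"""Contrast engine: gates, ANOVA, pairwise t, correction, categorization, summary."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from concord.contrast import (
    ChangeCategory,
    WeakerFlag,
    asd_weaker_flags,
    categorize_changes,
    correct_multiple,
    omnibus_anova,
    pairwise_ttests,
    pooled_ttest,
    positivity_gate,
    run_group_contrast,
    summarize_table1,
)


class TestPositivityGate:
    def test_strongly_positive_voxel_retained(self, rng):
        z = 5.0 + 0.1 * rng.standard_normal((20, 3))
        assert positivity_gate(z).all()

    def test_zero_mean_voxel_rejected(self, rng):
        z = rng.standard_normal((50, 1))
        z -= z.mean(axis=0)
        assert not positivity_gate(z, n_tests=1)[0]

    def test_bonferroni_arithmetic(self, rng):
        # raw p = 0.0002 with 100 voxels tested: 0.02 > 0.01 -> rejected
        n = 30
        t_needed = stats.t.isf(0.0002, df=n - 1)
        z = np.zeros((n, 1))
        z[:, 0] = rng.standard_normal(n)
        z[:, 0] = (z[:, 0] - z[:, 0].mean()) / z[:, 0].std(ddof=1)
        z[:, 0] = z[:, 0] + t_needed / np.sqrt(n)  # sample t exactly t_needed
        raw_p = stats.ttest_1samp(z[:, 0], 0, alternative="greater").pvalue
        assert raw_p == pytest.approx(0.0002, rel=1e-6)
        assert not positivity_gate(z, n_tests=100)[0]
        assert positivity_gate(z, n_tests=10)[0]

    def test_zero_variance_voxels(self):
        z = np.column_stack([np.full(10, 2.0), np.full(10, -1.0)])
        gate = positivity_gate(z, n_tests=2)
        assert gate[0] and not gate[1]


class TestAnova:
    def test_identical_groups_fail(self):
        x = np.tile(np.arange(30.0)[:, None], (3, 1))
        g = np.repeat(["HC", "SZ", "ASD"], 30)
        out = omnibus_anova(x, g, alpha=0.05)
        assert not out["passed"].iloc[0]
        assert out["p"].iloc[0] > 0.9

    def test_separated_groups_pass(self, rng):
        x = np.concatenate(
            [rng.normal(0, 1, 100), rng.normal(1, 1, 100), rng.normal(2, 1, 100)]
        )[:, None]
        g = np.repeat(["HC", "SZ", "ASD"], 100)
        assert omnibus_anova(x, g, alpha=0.001, correction="BFN")["passed"].iloc[0]

    def test_null_type_one_error_rate(self, rng):
        x = rng.standard_normal((90, 2000))
        g = np.repeat(["HC", "SZ", "ASD"], 30)
        rate = omnibus_anova(x, g, alpha=0.05)["passed"].mean()
        assert 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / 2000) < rate
        assert rate < 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / 2000)

    def test_tiny_group_rejected(self, rng):
        x = rng.standard_normal((5, 1))
        g = np.array(["HC", "HC", "SZ", "SZ", "ASD"])
        with pytest.raises(ValueError):
            omnibus_anova(x, g, 0.05)


class TestPairwiseT:
    def test_sign_convention_hc_higher_gives_positive_t(self, rng):
        x = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])[:, None]
        g = np.repeat(["HC", "SZ"], 50)
        out = pairwise_ttests(x, g)
        assert out["t_hc_sz"].iloc[0] > 0

    def test_identical_samples_degenerate(self):
        x = np.tile([[1.0], [2.0], [3.0]], (2, 1))
        t, p, flag = pooled_ttest(x[:3], x[3:])
        assert t[0] == 0 and p[0] == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        # two samples of n=3: a=(1,2,3), b=(2,4,6); hand-computed pooled t
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[2.0], [4.0], [6.0]])
        t, p, _ = pooled_ttest(a, b)
        sp2 = ((2 * 1.0) + (2 * 4.0)) / 4  # pooled variance 2.5
        t_hand = (2.0 - 4.0) / np.sqrt(sp2 * (2 / 3))
        assert t[0] == pytest.approx(t_hand, abs=1e-12)
        assert p[0] == pytest.approx(2 * stats.t.sf(abs(t_hand), df=4), abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        a = rng.standard_normal((20, 5))
        b = rng.standard_normal((25, 5)) + 0.4
        t, p, _ = pooled_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert np.allclose(t, ref.statistic)
        assert np.allclose(p, ref.pvalue)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_swapping_groups_negates_t_preserves_p(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal((10, 3)), r.standard_normal((12, 3))
        t1, p1, _ = pooled_ttest(a, b)
        t2, p2, _ = pooled_ttest(b, a)
        assert np.allclose(t1, -t2)
        assert np.allclose(p1, p2)


class TestCorrection:
    def test_single_test_reduces_to_alpha(self):
        assert correct_multiple(np.array([0.04]), "BFN", 0.05)[0]
        assert correct_multiple(np.array([0.04]), "FDR", 0.05)[0]
        assert not correct_multiple(np.array([0.06]), "BFN", 0.05)[0]

    def test_bh_stepup_by_hand(self):
        # BH at 0.05: thresholds k/4*0.05 = .0125,.025,.0375,.05
        # sorted p (.001,.02,.03,.9): largest k with p_k <= k/m*alpha is k=3
        flags = correct_multiple(np.array([0.001, 0.02, 0.03, 0.9]), "FDR", 0.05)
        assert list(flags) == [True, True, True, False]

    def test_all_ones_nothing_flagged(self):
        assert not correct_multiple(np.ones(10), "FDR", 0.05).any()
        assert not correct_multiple(np.ones(10), "BFN", 0.05).any()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            correct_multiple(np.array([]), "BFN", 0.05)


class TestCategorization:
    def test_exhaustive_sign_grid_matches_truth_table(self):
        """Brute-force enumeration over {-,0,+}^2 against an independent oracle."""

        def oracle(a, b):
            if a == 0 or b == 0:
                return ChangeCategory.NONE
            if a > 0 and b > 0:
                return ChangeCategory.COMMON_DECREASE
            if a < 0 and b < 0:
                return ChangeCategory.COMMON_INCREASE
            return (
                ChangeCategory.SZ_UNIQUE_DECREASE
                if a > 0
                else ChangeCategory.ASD_UNIQUE_DECREASE
            )

        values = [-2.1, 0.0, 1.3]
        for a, b in itertools.product(values, repeat=2):
            got = categorize_changes([a], [b], [True])[0]
            assert got is oracle(a, b), (a, b)

    def test_anova_failures_are_none(self):
        cats = categorize_changes([2.0, 2.0], [1.0, 1.0], [False, True])
        assert cats[0] is ChangeCategory.NONE
        assert cats[1] is ChangeCategory.COMMON_DECREASE

    def test_weaker_flags_by_category(self):
        cats = [
            ChangeCategory.COMMON_DECREASE,
            ChangeCategory.COMMON_INCREASE,
            ChangeCategory.COMMON_INCREASE,
            ChangeCategory.SZ_UNIQUE_DECREASE,
        ]
        flags = asd_weaker_flags([-0.7, -0.7, 0.7, -0.7], cats)
        assert flags == [
            WeakerFlag.ASD_WEAKER,
            WeakerFlag.NOT_WEAKER,
            WeakerFlag.ASD_WEAKER,
            WeakerFlag.NOT_APPLICABLE,
        ]

    def test_zero_t_is_not_weaker(self):
        flags = asd_weaker_flags(
            [0.0, 0.0], [ChangeCategory.COMMON_DECREASE, ChangeCategory.COMMON_INCREASE]
        )
        assert all(f is WeakerFlag.NOT_WEAKER for f in flags)

    def test_every_passing_feature_gets_exactly_one_category(self, rng):
        t1, t2 = rng.standard_normal(500), rng.standard_normal(500)
        cats = categorize_changes(t1, t2, np.ones(500, bool))
        assert all(isinstance(c, ChangeCategory) for c in cats)
        non_none = [c for c in cats if c is not ChangeCategory.NONE]
        assert len(non_none) == 500  # continuous T-values never tie at zero


class TestSummary:
    def test_percentage_arithmetic(self):
        counts = {
            ChangeCategory.COMMON_DECREASE: 2592,
            ChangeCategory.COMMON_INCREASE: 2906,
            ChangeCategory.SZ_UNIQUE_DECREASE: 1013,
            ChangeCategory.ASD_UNIQUE_DECREASE: 782,
        }
        weaker = {
            ChangeCategory.COMMON_DECREASE: 2212,
            ChangeCategory.COMMON_INCREASE: 2744,
        }
        summary = summarize_table1(counts, weaker, total_passing=7293)
        assert summary.percentages[ChangeCategory.COMMON_DECREASE] == 35.5
        assert summary.percentages[ChangeCategory.SZ_UNIQUE_DECREASE] == 13.9
        assert summary.weaker_percentages[ChangeCategory.COMMON_INCREASE] == 94.4

    def test_all_none_gives_zero_percentages(self):
        summary = summarize_table1([ChangeCategory.NONE] * 10)
        assert all(p == 0.0 for p in summary.percentages.values())

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            summarize_table1([], total_passing=0)

    def test_counts_sum_bounded_by_total(self, rng):
        t1, t2, t3 = (rng.standard_normal(200) for _ in range(3))
        passing = rng.random(200) < 0.5
        cats = categorize_changes(t1, t2, passing)
        weaker = asd_weaker_flags(t3, cats)
        summary = summarize_table1(cats, weaker, anova_pass=passing)
        cat_total = sum(
            n for c, n in summary.counts.items() if c is not ChangeCategory.NONE
        )
        assert cat_total <= summary.total_passing == passing.sum()


class TestEndToEnd:
    def test_planted_cohort_recovery(self, multisite_cohort, multisite_spec):
        from concord.harmonize import harmonize

        mm, cov, truth = multisite_cohort
        h = harmonize(mm, cov)
        res = run_group_contrast(h.values, cov["group"], family="fnc_edge")
        tab = res.table.set_index("feature")
        n_effects = len(multisite_spec.effect_plan)
        hits = sum(
            tab.loc[f"f{fid:04d}", "category"] == cat.value
            for fid, cat in truth.categories.items()
        )
        assert hits / n_effects >= 0.9
        common = tab.loc[
            [f"f{fid:04d}" for fid in truth.asd_weaker],
        ]
        recovered_common = common[common["category"].isin(
            ["common_decrease", "common_increase"]
        )]
        assert (recovered_common["weaker"] == "asd_weaker").mean() >= 0.9
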