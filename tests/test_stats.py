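import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pelvimarrow.stats import (
    ContingencyTable,
    build_table3,
    chi2_test,
    compare_continuous,
    fisher_exact,
    holm_bonferroni,
    ks_normality,
    logistic_fit,
    paired_change,
)
from pelvimarrow.synthetic_data import realize_table3_cohort, simulate_logistic_cohort


def pearson_chi2_oracle(counts):
    """Textbook sum((O - E)^2 / E)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    e = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    return float(((counts - e) ** 2 / e).sum())


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumeration over tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestKSNormality:
    def test_normal_sample_usually_passes(self):
        hits = sum(
            ks_normality(np.random.default_rng(seed).normal(size=500)).p_value >= 0.05
            for seed in range(20)
        )
        assert hits >= 18  # 5% nominal type-I error

    def test_uniform_sample_fails(self, rng):
        x = rng.uniform(0, 10, size=500)
        assert ks_normality(x).p_value < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ks_normality([3.0, 3.0, 3.0, 3.0])

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="4"):
            ks_normality([1.0, 2.0, 3.0])


class TestCompareContinuous:
    def test_identical_groups_give_p_1(self, rng):
        x = rng.normal(size=40)
        res = compare_continuous(x, x.copy())
        assert res.p_value == pytest.approx(1.0)
        assert abs(res.statistic) < 1e-12

    def test_t_statistic_matches_hand_formula(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
        res = compare_continuous(x, y, method="t")
        nx, ny = 3, 3
        sp2 = (np.var(x, ddof=1) * (nx - 1) + np.var(y, ddof=1) * (ny - 1)) / (nx + ny - 2)
        t_hand = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)

    def test_mann_whitney_fully_separated_matches_enumeration(self):
        """x=[1,2,3], y=[4,5,6]: U=0 and the exact one-sided level is 1/20."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_continuous(x, y, method="mann_whitney")
        # enumeration over all C(6,3)=20 rank assignments of group A
        # (0-based ranks): U1 = rank sum - n1(n1+1)/2; only one gives U1 = 0
        u_values = [sum(comb) - 3 for comb in itertools.combinations(range(6), 3)]
        assert sum(u == 0 for u in u_values) / 20 == 1 / 20
        # the reported Z corresponds to U=0 at n1=n2=3 without ties:
        # Z = (0 - 4.5) / sqrt(3*3*7/12)
        assert res.statistic == pytest.approx(-4.5 / np.sqrt(9 * 7 / 12), rel=1e-12)
        from scipy.stats import mannwhitneyu

        expect = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(expect.pvalue, rel=1e-9)

    def test_tie_corrected_z_matches_scipy(self, rng):
        x = rng.integers(0, 5, size=25).astype(float)
        y = rng.integers(1, 6, size=30).astype(float)
        from scipy.stats import mannwhitneyu

        expect = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
        res = compare_continuous(x, y, method="mann_whitney")
        assert res.p_value == pytest.approx(expect.pvalue, rel=1e-9)

    def test_gate_is_deterministic(self, rng):
        x = rng.normal(size=60)
        y = rng.exponential(size=60)
        methods = {compare_continuous(x, y).method for _ in range(3)}
        assert len(methods) == 1


class TestPairedChange:
    def test_no_change_gives_p_1(self):
        b = [5.0, 6.0, 7.0, 8.0]
        res = paired_change(b, b)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_signed_rank_statistic_with_tied_ranks(self):
        """Differences [1, 2, 3, -1]: W computed by hand with tied ranks."""
        res = paired_change([10.0, 10.0, 10.0, 10.0], [9.0, 8.0, 7.0, 11.0], method="wilcoxon")
        # |d| = 1, 2, 3, 1 -> ranks 1.5, 3, 4, 1.5; W = min(8.5, 1.5)
        assert res.statistic == pytest.approx(1.5)
        assert 0 < res.p_value <= 1

    def test_signed_rank_exact_p_matches_sign_enumeration(self):
        """Tie-free differences [1, 2, 3, -4]: exact p over all 2^4 sign flips."""
        base = [10.0] * 4
        nad = [9.0, 8.0, 7.0, 14.0]
        res = paired_change(base, nad, method="wilcoxon")
        ranks = [1, 2, 3, 4]
        w_obs = min(1 + 2 + 3, 4)  # w_plus, w_minus
        assert res.statistic == pytest.approx(w_obs)
        more_extreme = sum(
            min(wp := sum(r for r, s in zip(ranks, signs) if s > 0), 10 - wp) <= w_obs
            for signs in itertools.product([1, -1], repeat=4)
        )
        assert res.p_value == pytest.approx(more_extreme / 16)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            paired_change([1, 2, 3], [1, 2])

    def test_paired_t_matches_scipy(self, rng):
        b = rng.normal(7, 1, size=30)
        n = b - rng.normal(3, 0.5, size=30)
        from scipy.stats import ttest_rel

        res = paired_change(b, n, method="paired_t")
        stat, p = ttest_rel(b, n)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)


class TestChi2:
    @pytest.mark.parametrize(
        "counts,correction,expected",
        [
            ([[10, 3], [3, 10]], "none", 7.538),
            ([[3, 10], [9, 6]], "none", 3.877),
            ([[10, 3], [9, 6]], "yates", 0.303),
        ],
    )
    def test_reference_pairwise_tables(self, counts, correction, expected):
        res = chi2_test(ContingencyTable(np.array(counts)), correction=correction)
        assert res.statistic == pytest.approx(expected, abs=5e-4)

    def test_auto_triggers_yates_below_expected_5(self):
        res = chi2_test(ContingencyTable(np.array([[10, 3], [9, 6]])), correction="auto")
        assert res.method == "chi2_yates" and res.correction
        res2 = chi2_test(ContingencyTable(np.array([[10, 3], [3, 10]])), correction="auto")
        assert res2.method == "chi2" and not res2.correction

    def test_identical_row_proportions_give_zero(self):
        res = chi2_test(ContingencyTable(np.array([[10, 20], [5, 10]])), correction="none")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_oracle_on_random_tables(self, rng):
        for _ in range(200):
            r, c = rng.integers(2, 5, size=2)
            counts = rng.integers(1, 30, size=(r, c))
            res = chi2_test(ContingencyTable(counts), correction="none")
            assert res.statistic == pytest.approx(pearson_chi2_oracle(counts), abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ContingencyTable(np.array([[0, 0], [3, 10]]))

    def test_yates_on_non_2x2_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            chi2_test(ContingencyTable(np.array([[1, 2], [3, 4], [5, 6]])), correction="yates")


class TestFisher:
    def test_diagonal_table(self):
        res = fisher_exact(ContingencyTable(np.array([[10, 0], [0, 10]])))
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_balanced_table_gives_1(self):
        res = fisher_exact(ContingencyTable(np.array([[5, 5], [5, 5]])))
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_on_random_small_tables(self, rng):
        for _ in range(150):
            a, b, c, d = rng.integers(1, 10, size=4)
            res = fisher_exact(ContingencyTable(np.array([[a, b], [c, d]])))
            assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact(ContingencyTable(np.array([[1, 2], [3, 4], [5, 6]])))


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03]) == pytest.approx([0.03])

    def test_reference_triplet(self):
        adj = holm_bonferroni([0.006, 0.049, 0.582])
        assert adj == pytest.approx([0.018, 0.098, 0.582])

    def test_all_equal_ps(self):
        adj = holm_bonferroni([0.02, 0.02, 0.02])
        assert adj == pytest.approx([0.06, 0.06, 0.06])

    def test_order_preserving_and_dominated_by_bonferroni(self, rng):
        p = rng.uniform(size=8)
        adj = holm_bonferroni(p)
        assert np.all(adj <= np.minimum(p * len(p), 1.0) + 1e-12)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestLogisticFit:
    def test_single_binary_predictor_recovers_cross_product_ratio(self):
        # expand the [[10,3],[3,10]] table into subject-level records
        x = [0] * 13 + [1] * 13
        y = [0] * 10 + [1] * 3 + [0] * 3 + [1] * 10
        fit = logistic_fit(pd.DataFrame({"g": x}), y)
        # OR = (10*10)/(3*3)
        assert fit.odds_ratio[1] == pytest.approx(100 / 9, rel=1e-6)
        assert fit.ci_low[1] < fit.odds_ratio[1] < fit.ci_high[1]

    def test_or_equals_exp_coef_and_wald_ci(self):
        df = simulate_logistic_cohort(400, seed=5)
        fit = logistic_fit(
            df[["suvmax", "bm_group"]], df["severe"], categorical={"bm_group": "MID30_40"}
        )
        np.testing.assert_allclose(fit.odds_ratio, np.exp(fit.coef), rtol=1e-12)
        np.testing.assert_allclose(fit.ci_low, np.exp(fit.coef - 1.959963984540054 * fit.se), rtol=1e-9)

    def test_null_model_cis_cover_1(self, rng):
        n = 2000
        df = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.integers(0, 2, size=n)
        fit = logistic_fit(df, y)
        assert fit.ci_low[1] < 1 < fit.ci_high[1]

    def test_complete_separation_raises(self):
        df = pd.DataFrame({"x": np.arange(20.0)})
        y = (df["x"] >= 10).astype(int)
        with pytest.raises(ValueError):
            logistic_fit(df, y)

    def test_missing_reference_level_rejected(self):
        df = pd.DataFrame({"g": ["a", "b"] * 10})
        with pytest.raises(ValueError, match="reference"):
            logistic_fit(df, [0, 1] * 10, categorical={"g": "z"})

    def test_one_class_outcome_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="both classes"):
            logistic_fit(df, [1] * 10)


@pytest.fixture(scope="module")
def cohort():
    return realize_table3_cohort(include_series=False)[0]


class TestBuildTable3:
    def test_pairwise_chi2_values(self, cohort):
        res = build_table3(cohort)
        chi2 = dict(zip(res["pairwise"]["pair"], res["pairwise"]["chi2"]))
        assert chi2["LT30 vs MID30_40"] == pytest.approx(7.538, abs=5e-4)
        assert chi2["MID30_40 vs GT40"] == pytest.approx(3.877, abs=5e-4)
        assert chi2["LT30 vs GT40"] == pytest.approx(0.303, abs=5e-4)

    def test_holm_adjustment_of_pairwise(self, cohort):
        res = build_table3(cohort)
        assert res["pairwise"]["p_holm"].tolist() == pytest.approx(
            holm_bonferroni(res["pairwise"]["p_raw"].to_numpy()).tolist()
        )

    def test_grouped_membership_screened(self, cohort):
        res = build_table3(cohort)
        assert "bm_group" in res["screened"]

    def test_invariant_to_row_order(self, cohort):
        shuffled = cohort.sample(frac=1, random_state=9).reset_index(drop=True)
        a = build_table3(cohort)
        b = build_table3(shuffled)
        pd.testing.assert_frame_equal(a["pairwise"], b["pairwise"])
        np.testing.assert_array_equal(a["crosstab"].counts, b["crosstab"].counts)

    def test_missing_columns_rejected(self, cohort):
        with pytest.raises(ValueError, match="missing"):
            build_table3(cohort.drop(columns=["suvmax"]))
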