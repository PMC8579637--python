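"""Statistics layer: test gates, ROC machinery, diagnostic identities."""

from math import comb

import numpy as np
import pytest

from qmripred.cohort_stats import (
    compare_categorical,
    compare_paired,
    compare_unpaired,
    delong_compare,
    diagnostic_metrics,
    logistic_combine,
    roc_analysis,
    t_from_summary,
)


class TestPairedComparison:
    def test_identical_pairs(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        gc = compare_paired(x, x)
        assert gc.statistic == 0.0 and gc.p_value == 1.0

    def test_detects_known_shift(self):
        """A 300-unit shift on 56 normal pairs is overwhelmingly significant."""
        rng = np.random.default_rng(2)
        pre = rng.normal(1238.0, 212.0, 56)
        post = pre + 300.0 + rng.normal(0, 60.0, 56)
        gc = compare_paired(pre, post)
        assert gc.test == "paired t" and gc.p_value < 1e-3
        assert "mean" in gc.summary_1

    def test_skewed_differences_take_rank_branch(self):
        rng = np.random.default_rng(4)
        pre = rng.lognormal(0.0, 1.0, 60)
        post = pre + rng.lognormal(0.5, 1.5, 60)
        gc = compare_paired(pre, post)
        assert gc.test == "Wilcoxon signed-rank"
        assert "median" in gc.summary_1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1, 2, 3], [1, 2])


class TestUnpairedComparison:
    def test_identical_skewed_groups(self):
        rng = np.random.default_rng(6)
        g = rng.lognormal(0.0, 1.2, 30)
        gc = compare_unpaired(g, g)
        assert gc.test == "Mann-Whitney U"
        assert gc.p_value == pytest.approx(1.0, abs=1e-9)

    def test_power_at_reported_group_moments(self):
        """Groups at the ADC-pre moments (n=36/20) separate at p<0.01
        in at least 95% of replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            g1 = rng.normal(1119.58, 144.06, 36)
            g2 = rng.normal(1386.25, 198.23, 20)
            if compare_unpaired(g1, g2).p_value < 0.01:
                hits += 1
        assert hits >= 190

    def test_agrees_with_summary_t(self):
        """Moment-matched samples reproduce the summary-statistic t."""
        rng = np.random.default_rng(8)

        def matched(mean, sd, n):
            x = rng.normal(0, 1, n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        g1 = matched(1119.58, 144.06, 36)
        g2 = matched(1386.25, 198.23, 20)
        gc = compare_unpaired(g1, g2)
        expected = t_from_summary(1119.58, 144.06, 36, 1386.25, 198.23, 20)
        assert abs(gc.statistic) == pytest.approx(expected, rel=1e-10)


class TestSummaryT:
    def test_equal_means_give_zero(self):
        assert t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    @pytest.mark.parametrize("args,expected", [
        # pooled t recomputed from published group summaries
        ((-64.98, 17.77, 36, -30.35, 14.94, 20), 7.377),  # volume change %
        ((1119.58, 144.06, 36, 1386.25, 198.23, 20), 5.790),  # ADC-pre
        ((43.75, 13.14, 36, 48.75, 11.92, 20), 1.41),  # age
    ])
    def test_reproduces_reported_statistics(self, args, expected):
        assert t_from_summary(*args) == pytest.approx(expected, abs=5e-3)


class TestCategorical:
    def test_proportional_table_is_null(self):
        gc = compare_categorical(np.array([[20, 10], [40, 20]]))
        assert gc.statistic == pytest.approx(0.0)
        assert gc.p_value == pytest.approx(1.0)

    def test_small_expected_uses_continuity_correction(self):
        gc = compare_categorical(np.array([[29, 7], [17, 3]]))
        assert "continuity" in gc.test
        assert gc.p_value > 0.05

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Perfectly diagonal 2x2: two-sided Fisher p is 2/C(20,10)."""
        gc = compare_categorical(np.array([[10, 0], [0, 10]]))
        assert gc.test == "Fisher exact"
        assert gc.p_value == pytest.approx(2.0 / comb(20, 10), rel=1e-9)

    def test_large_balanced_table_uses_plain_chisquare(self):
        gc = compare_categorical(np.array([[30, 25], [20, 25]]))
        assert gc.test == "chi-square"

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical(np.array([[1.5, 2.0], [3.0, 4.0]]))


class TestLogisticCombination:
    def test_separable_data_flagged_but_usable(self):
        x = np.array([1.0, 2, 3, 10, 11, 12])
        y = np.array([0, 0, 0, 1, 1, 1])
        combo = logistic_combine(x, y)
        assert combo.separation
        assert roc_analysis(combo.scores, y).auc == 1.0

    def test_coefficient_signs_follow_orientation(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 80)
        X = np.column_stack([y + rng.normal(0, 0.05, 80),
                             -2.0 * y + rng.normal(0, 0.05, 80)])
        combo = logistic_combine(X, y)
        assert combo.coefficients[0] > 0 > combo.coefficients[1]

    def test_constant_feature_has_zero_coefficient(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 15)
        X = np.column_stack([np.full(30, 3.7), y + rng.normal(0, 0.5, 30)])
        combo = logistic_combine(X, y)
        assert abs(combo.coefficients[0]) < 1e-8

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            logistic_combine(np.arange(5.0), np.ones(5, int))


class TestRocAnalysis:
    def test_small_example_by_pair_counting(self):
        """positives {2,4} vs negatives {1,3}: 3 of 4 pairs concordant."""
        r = roc_analysis(np.array([2.0, 4.0, 1.0, 3.0]),
                         np.array([1, 1, 0, 0]))
        assert r.auc == 0.75

    def test_perfect_separation(self):
        r = roc_analysis(np.array([1.0, 2, 3, 10, 11]),
                         np.array([0, 0, 0, 1, 1]))
        assert r.auc == 1.0 and r.youden == 1.0
        assert 3.0 < r.cutoff < 10.0
        assert np.isinf(r.plr)

    def test_auc_equals_mannwhitney_and_youden_is_bruteforce_max(self):
        """Trapezoid AUC = U/(n1 n2) and the returned cutoff attains the
        exhaustive-scan Youden maximum, on 100 random tied instances."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n1, n0 = rng.integers(3, 15, 2)
            scores = np.concatenate([rng.integers(0, 8, n1),
                                     rng.integers(0, 8, n0)]).astype(float)
            y = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
            r = roc_analysis(scores, y)
            s = scores if r.orientation == "higher" else -scores
            # exhaustive concordant-pair count, ties half
            pos, neg = s[y], s[~y]
            diff = pos[:, None] - neg[None, :]
            u = (diff > 0).sum() + 0.5 * (diff == 0).sum()
            assert r.auc == pytest.approx(u / (n1 * n0), abs=1e-12)
            # brute-force Youden over every possible threshold
            best = max(
                ((s >= c) & y).sum() / y.sum() + ((s < c) & ~y).sum() / (~y).sum() - 1.0
                for c in np.concatenate([s - 1e-9, s + 1e-9]))
            assert r.youden == pytest.approx(best, abs=1e-12)

    def test_orientation_recorded_for_inverse_marker(self):
        rng = np.random.default_rng(12)
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        y = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
        r = roc_analysis(scores, y)
        assert r.orientation == "lower" and r.auc > 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(4.0), np.ones(4, bool))


class TestDiagnosticMetrics:
    @pytest.mark.parametrize("sens,spec,youden,plr,nlr,ppv,npv", [
        # published operating points at prevalence 36/20
        (0.75, 0.90, 0.650, 7.50, 0.28, 93.1, 66.7),
        (0.806, 0.75, 0.556, 3.22, 0.26, 85.3, 68.2),
        (0.944, 0.45, 0.394, 1.72, 0.12, 75.6, 81.8),
        (0.75, 0.70, 0.450, 2.50, 0.36, 81.8, 60.9),
        (0.7222, 0.95, 0.672, 14.44, 0.29, 96.3, 65.5),
    ])
    def test_operating_point_identities(self, sens, spec, youden, plr, nlr, ppv, npv):
        dm = diagnostic_metrics(sens, spec, 36, 20)
        assert dm.youden == pytest.approx(youden, abs=5e-4)
        assert dm.plr == pytest.approx(plr, abs=5e-3)
        assert dm.nlr == pytest.approx(nlr, abs=5e-3)
        assert dm.ppv_pct == pytest.approx(ppv, abs=0.05)
        assert dm.npv_pct == pytest.approx(npv, abs=0.05)

    def test_perfect_test(self):
        dm = diagnostic_metrics(1.0, 1.0, 10, 10)
        assert dm.youden == 1.0 and dm.nlr == 0.0
        assert np.isinf(dm.plr)
        assert dm.ppv_pct == 100.0 and dm.npv_pct == 100.0


class TestDelong:
    def _cohort(self, seed=13):
        rng = np.random.default_rng(seed)
        y = np.concatenate([np.ones(36, bool), np.zeros(20, bool)])
        s = np.concatenate([rng.normal(1, 1, 36), rng.normal(0, 1, 20)])
        return s, y

    def test_self_comparison_is_null(self):
        s, y = self._cohort()
        diff, z, p = delong_compare(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_rank_invariance(self):
        s, y = self._cohort()
        diff, _, p = delong_compare(s, np.exp(s), y)
        assert diff == 0.0 and p == 1.0

    def test_detects_dominant_marker(self):
        rng = np.random.default_rng(14)
        y = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        strong = y + rng.normal(0, 0.4, 100)
        weak = rng.normal(0, 1, 100)
        diff, z, p = delong_compare(strong, weak, y)
        assert diff > 0.2 and p < 0.01
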