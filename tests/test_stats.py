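"""Unit, oracle, and simulation tests for the diagnostic-statistics module."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as hst
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from adcr.stats import (
    ConfusionCounts,
    auc_band,
    auc_ci,
    categorical_tests,
    clopper_pearson,
    confusion_at_rule,
    delong_covariance,
    delong_test,
    delong_variance,
    diagnostic_metrics,
    empirical_auc,
    kruskal_wallis_with_posthoc,
    mann_whitney,
    roc_analysis,
    zero_fpr_cutoff,
)


def _brute_force_auc(pos, neg):
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEmpiricalAUC:
    def test_pairwise_example(self):
        assert empirical_auc([3, 5], [1, 4]) == pytest.approx(0.75)

    def test_identical_groups_give_half(self):
        assert empirical_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert empirical_auc([10, 11], [1, 2]) == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1])

    @given(
        pos=hst.lists(hst.integers(0, 8), min_size=1, max_size=12),
        neg=hst.lists(hst.integers(0, 8), min_size=1, max_size=12),
    )
    def test_matches_bruteforce_and_sklearn(self, pos, neg):
        expected = _brute_force_auc(pos, neg)
        assert empirical_auc(pos, neg) == pytest.approx(expected, abs=1e-12)
        y = [1] * len(pos) + [0] * len(neg)
        assert roc_auc_score(y, pos + neg) == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        pos, neg = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
        f = lambda v: np.exp(3 * np.asarray(v)) + 7
        assert empirical_auc(f(pos), f(neg)) == pytest.approx(empirical_auc(pos, neg))
        assert delong_variance(f(pos), f(neg)) == pytest.approx(delong_variance(pos, neg))


class TestDeLong:
    def test_hand_computed_variance(self):
        # V10 = {0.5, 1.0}, V01 = {1.0, 0.5}: var = 0.125/2 + 0.125/2
        assert delong_variance([3, 5], [1, 4]) == pytest.approx(0.125)

    def test_perfect_separation_gives_zero_variance(self):
        assert delong_variance([10, 11, 12], [1, 2, 3]) == 0.0

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            delong_variance([1], [2, 3])

    def test_paired_self_comparison_is_null(self, rng):
        for _ in range(5):
            m = rng.normal(size=40)
            y = rng.random(40) < 0.5
            y[:2] = [True, False]  # both classes present
            res = delong_test(m, m, y, design="paired")
            assert res.z == 0.0 and res.p == 1.0

    def test_z_sign_matches_auc_difference(self, rng):
        y = np.repeat([True, False], 30)
        strong = np.r_[rng.normal(2, 1, 30), rng.normal(0, 1, 30)]
        weak = rng.normal(size=60)
        res = delong_test(strong, weak, y, design="paired")
        assert (res.auc_a - res.auc_b) * res.z > 0

    def test_paired_power_on_anticorrelated_markers(self, rng):
        """An informative marker (AUC ~0.9) beats pure noise at n=50+50."""
        hits = 0
        for _ in range(25):
            signal = np.repeat([1.8, 0.0], 50)
            noise = rng.normal(size=100)
            marker_a = signal + noise
            marker_b = -noise  # anti-correlated with marker_a, AUC ~0.5
            y = np.repeat([True, False], 50)
            if delong_test(marker_a, marker_b, y, design="paired").p < 0.05:
                hits += 1
        assert hits > 20  # > 80% power

    def test_unpaired_type_i_error_calibrated(self, rng):
        """Same-distribution cohorts: rejection rate ~ alpha."""
        lab = np.repeat([True, False], 60)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = np.r_[rng.beta(8, 24, 60), rng.beta(4, 28, 60)]
            b = np.r_[rng.beta(8, 24, 60), rng.beta(4, 28, 60)]
            res = delong_test(a, b, lab, design="unpaired", labels_b=lab)
            rejections += res.p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_covariance_of_identical_markers_equals_variance(self, rng):
        pos, neg = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
        assert delong_covariance(pos, neg, pos, neg) == pytest.approx(
            delong_variance(pos, neg)
        )


class TestAucCI:
    def test_zero_variance_collapses(self):
        assert auc_ci(0.8, 0.0) == (0.8, 0.8)

    def test_upper_clipped_to_one(self):
        lo, hi = auc_ci(0.99, 0.01)
        assert hi == 1.0 and lo < 0.99

    def test_wald_interval(self):
        lo, hi = auc_ci(0.8, 0.0025)
        assert lo == pytest.approx(0.702, abs=5e-4)
        assert hi == pytest.approx(0.898, abs=5e-4)


class TestROCAnalysis:
    def test_curve_endpoints_and_monotonicity(self, rng):
        roc = roc_analysis(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        fpr = [p[0] for p in roc.curve]
        tpr = [p[1] for p in roc.curve]
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))

    def test_auc_equals_trapezoidal_area(self, rng):
        roc = roc_analysis(rng.normal(1, 1, 40), rng.normal(0, 1, 40))
        fpr = np.array([p[0] for p in roc.curve])
        tpr = np.array([p[1] for p in roc.curve])
        assert roc.auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)


class TestZeroFPRCutoff:
    def test_hand_example(self):
        cut = zero_fpr_cutoff([1, 2, 3], [2.5, 4, 5])
        assert cut.cutoff_value == 3.0
        assert cut.rule == "marker > 3"
        assert cut.derivation_sensitivity == pytest.approx(2 / 3)

    def test_degenerate_separation_keeps_specificity(self):
        cut = zero_fpr_cutoff([5, 6], [1, 2])
        assert cut.derivation_sensitivity == 0.0

    def test_tie_with_good_maximum_is_rule_negative(self):
        cut = zero_fpr_cutoff([1, 4], [4, 9])
        assert cut.derivation_sensitivity == pytest.approx(0.5)

    def test_fp_always_zero_on_derivation_sample(self, rng):
        for _ in range(20):
            good = rng.normal(0, 2, 30)
            poor = rng.normal(1, 2, 40)
            cut = zero_fpr_cutoff(good, poor)
            counts = confusion_at_rule(
                np.r_[poor, good], np.r_[np.ones(40), np.zeros(30)].astype(bool),
                cut.cutoff_value,
            )
            assert counts.fp == 0


class TestConfusionAndMetrics:
    def test_rule_below_everything(self):
        counts = confusion_at_rule([1, 2, 3], [True, False, True], -np.inf)
        assert counts.fn == 0 and counts.tn == 0

    def test_hand_counts(self):
        counts = confusion_at_rule([1, 2, 3], [False, False, True], 2)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 0, 0, 2)

    def test_sensitivity_from_published_style_counts(self):
        perf = diagnostic_metrics(ConfusionCounts(tp=127, fp=53, fn=11, tn=33))
        assert perf.sensitivity == pytest.approx(92.0, abs=0.05)

    def test_perfect_specificity_ci(self):
        perf = diagnostic_metrics(ConfusionCounts(tp=105, fp=0, fn=33, tn=86))
        assert perf.specificity == 100.0
        assert perf.specificity_ci[0] == pytest.approx(95.8, abs=0.05)

    def test_undefined_ratio_is_nan_not_zero(self):
        perf = diagnostic_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert math.isnan(perf.ppv)
        assert perf.specificity == 100.0


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo", [(86, 86, 0.958), (28, 28, 0.877), (65, 65, 0.945)]
    )
    def test_all_successes_lower_bound_closed_form(self, k, n, lo):
        assert clopper_pearson(k, n)[0] == pytest.approx(0.025 ** (1 / n), abs=1e-12)
        assert round(clopper_pearson(k, n)[0], 3) == lo

    def test_zero_successes(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)

    @pytest.mark.parametrize("p", [0.05, 0.5, 0.95])
    @pytest.mark.parametrize("n", [20, 100])
    def test_coverage_at_least_nominal(self, p, n, rng):
        """Exact intervals are conservative: >= 95% empirical coverage."""
        intervals = np.array([clopper_pearson(k, n) for k in range(n + 1)])
        ks = rng.binomial(n, p, size=2000)
        covered = (intervals[ks, 0] <= p) & (p <= intervals[ks, 1])
        assert covered.mean() >= 0.95


class TestGroupComparisons:
    def test_mann_whitney_identical_groups(self):
        res = mann_whitney([1.0, 2.0, 3.0] * 10, [1.0, 2.0, 3.0] * 10)
        assert res.p == pytest.approx(1.0)
        assert res.u == pytest.approx(30 * 30 / 2)

    def test_mann_whitney_full_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u in (0.0, 9.0)

    def test_mann_whitney_type_i_error(self, rng):
        rejections = sum(
            mann_whitney(rng.normal(size=30), rng.normal(size=30)).p < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_kruskal_identical_groups_nothing_flagged(self):
        res = kruskal_wallis_with_posthoc([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.h == pytest.approx(0.0)
        assert not any(c.significant for c in res.pairwise)

    def test_bonferroni_threshold(self):
        res = kruskal_wallis_with_posthoc([[1, 2], [3, 4], [5, 6]])
        assert res.bonferroni_alpha == pytest.approx(0.05 / 3)

    def test_kruskal_h_matches_hand_ranked_oracle(self):
        # ranks 1..6, rank sums 3/7/11: H = 12/(6*7) * sum(R^2/2) - 3*7
        res = kruskal_wallis_with_posthoc([[1, 2], [3, 4], [5, 6]])
        assert res.h == pytest.approx(12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21)

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis_with_posthoc([[1], [2]])


class TestCategorical:
    def test_balanced_table_p_one(self):
        assert categorical_tests([[10, 10], [10, 10]]).p == pytest.approx(1.0)

    def test_fisher_exact_enumeration(self):
        res = categorical_tests([[5, 0], [0, 5]])
        assert res.method == "fisher"
        # hypergeometric: only the observed table and its mirror are as extreme
        assert res.p == pytest.approx(2 / 252, abs=1e-9)

    def test_expected_cell_rule_boundary(self):
        # expected cells exactly 5 -> chi-square; just below -> Fisher
        assert categorical_tests([[1, 9], [9, 1]]).method == "chi2"
        assert categorical_tests([[1, 8], [9, 2]]).method == "fisher"

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            categorical_tests([[0, 0], [3, 4]])


class TestAucBand:
    @pytest.mark.parametrize(
        "auc,label",
        [
            (0.909, "excellent"),
            (0.90, "excellent"),
            (0.89, "good"),
            (0.70, "fair"),
            (0.69, "poor"),
            (0.50, "poor"),
            (0.49, "worse than chance"),
        ],
    )
    def test_band_labels(self, auc, label):
        assert auc_band(auc) == label
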