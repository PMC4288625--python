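"""ROC/AUC, Youden thresholding, confusion metrics and the rank-sum test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bprsig import (confusion_metrics, evaluate_predictions, roc_auc,
                    wilcoxon_rank_sum, youden_threshold)
from bprsig.metrics import roc_curve


def _brute_force_auc(probs, labels):
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.4], [1, 1, 0]) == 1.0

    def test_all_tied_probabilities(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_enumerated_four_pairs(self):
        assert roc_auc([0.9, 0.35, 0.3, 0.4], [1, 1, 0, 0]) == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.floats(0, 1, allow_nan=False),
                              st.integers(0, 1)), min_size=4, max_size=200))
    def test_matches_pair_enumeration(self, pairs):
        probs = [p for p, _ in pairs]
        labels = [y for _, y in pairs]
        if sum(labels) in (0, len(labels)):
            labels[0], labels[1] = 0, 1
        assert roc_auc(probs, labels) == pytest.approx(
            _brute_force_auc(probs, labels), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random(20)
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[:2] = [0, 1]
        assert roc_auc(probs, labels) + roc_auc(1 - probs, labels) == \
               pytest.approx(1.0, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestYouden:
    def test_scan_of_four_candidates(self):
        t, j = youden_threshold([0.9, 0.6, 0.5, 0.2], [1, 1, 0, 0])
        assert t == pytest.approx(0.6)
        assert j == pytest.approx(1.0)

    def test_perfect_separation_reaches_j_one(self):
        _, j = youden_threshold([0.99, 0.98, 0.01, 0.02], [1, 1, 0, 0])
        assert j == pytest.approx(1.0)

    def test_ties_resolve_to_larger_threshold(self):
        # thresholds 0.4 and 0.8 both give J = 0.5; the larger must win
        probs = [0.8, 0.4, 0.4, 0.1]
        labels = [1, 1, 0, 0]
        t, j = youden_threshold(probs, labels)
        assert j == pytest.approx(0.5)
        assert t == pytest.approx(0.8)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_j_equals_max_over_roc_curve(self, seed):
        rng = np.random.default_rng(seed)
        probs = np.round(rng.random(30), 2)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[:2] = [0, 1]
        _, j = youden_threshold(probs, labels)
        best = max(
            (np.mean(probs[labels == 1] >= t)
             + np.mean(probs[labels == 0] < t) - 1)
            for t in np.unique(probs))
        assert j == pytest.approx(best, abs=1e-12)


class TestConfusionMetrics:
    def test_all_correct_gives_unit_rates(self):
        report = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert (report.sensitivity, report.specificity, report.ppv,
                report.npv, report.accuracy) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_random_instance_matches_recount(self):
        rng = np.random.default_rng(9)
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        t = 0.45
        report = confusion_metrics(probs, labels, t)
        call = probs >= t
        tp = int(np.sum(call & (labels == 1)))
        fp = int(np.sum(call & (labels == 0)))
        tn = int(np.sum(~call & (labels == 0)))
        fn = int(np.sum(~call & (labels == 1)))
        assert report.confusion == (tp, fp, tn, fn)
        assert report.accuracy == pytest.approx((tp + tn) / 50)
        assert report.sensitivity == pytest.approx(tp / (tp + fn))
        assert report.ppv == pytest.approx(tp / (tp + fp))

    def test_undefined_rates_reported_absent(self):
        # threshold above every probability: nothing called positive
        report = confusion_metrics([0.1, 0.2, 0.3], [1, 1, 0], 0.9)
        assert report.ppv is None
        assert report.sensitivity == 0.0
        assert report.npv == pytest.approx(1 / 3)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([0.5], [1, 0][:1], 1.5)


class TestWilcoxon:
    def test_exact_enumeration_three_vs_three(self):
        # all 20 label assignments: the observed split is one of the two
        # extreme rankings, two-sided p = 2/20
        assert wilcoxon_rank_sum([1, 2, 3, 4, 5, 6],
                                 [1, 1, 1, 0, 0, 0]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 1.0, 2.0],
                                 [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_normal_approximation_close_to_exact(self):
        from bprsig.metrics import wilcoxon_rank_sum as wrs

        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(20):
            a = rng.normal(0.0, 1.0, 9)
            b = rng.normal(0.0, 1.0, 9)
            # force the approximation branch by exceeding the exact-size cap
            # with rank-extreme sentinels added symmetrically to both groups
            values = np.concatenate([a, b, [50.0, -50.0]])
            labels = np.concatenate([np.ones(9, int), np.zeros(9, int), [1, 0]])
            approx = wrs(values, labels)
            exact = stats.mannwhitneyu(values[labels == 1], values[labels == 0],
                                       alternative="two-sided",
                                       method="exact").pvalue
            worst = max(worst, abs(exact - approx))
        assert worst < 0.02

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([0.4, 0.5], [1, 1])


class TestEvaluatePredictions:
    def test_report_combines_auc_threshold_and_p(self):
        probs = [0.95, 0.9, 0.8, 0.76, 0.3, 0.2, 0.6, 0.1]
        labels = [1, 1, 1, 1, 1, 0, 0, 0]
        report = evaluate_predictions(probs, labels)
        assert report.auc == pytest.approx(roc_auc(probs, labels))
        t, _ = youden_threshold(probs, labels)
        assert report.threshold == pytest.approx(t)
        assert 0 < report.wilcoxon_p <= 1

    def test_fixed_threshold_respected(self):
        report = evaluate_predictions([0.9, 0.5, 0.1, 0.3], [1, 1, 0, 0],
                                      threshold=0.74)
        assert report.threshold == 0.74
        assert report.confusion == (1, 0, 2, 1)

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(23)
        probs = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        curve = roc_curve(probs, labels)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)
        assert curve[-1, 0] == 1.0 and curve[-1, 1] == 1.0
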