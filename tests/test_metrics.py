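"""Metric formulas, multiclass averaging and ROC/AUC.

Expected values are produced by independent direct evaluation of the
ratio definitions (plain arithmetic in the tests) and, for AUC, by a
brute-force count of concordant score pairs.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepeeg.metrics import (
    ConfusionCounts,
    MetricError,
    average_metric_sets,
    binary_metrics,
    confusion_counts,
    confusion_matrix,
    metrics_from_predictions,
    multiclass_metrics,
    roc_curve_auc,
)


def _direct_metrics(tp, fn, tn, fp):
    """Independent evaluation of the seven ratio formulas, in percent."""
    def ratio(n, d):
        return None if d == 0 else 100.0 * n / d

    mcc_den = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    return {
        "SEN": ratio(tp, tp + fn),
        "SPF": ratio(tn, tn + fp),
        "ACC": ratio(tp + tn, tp + tn + fn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "MCC": None if mcc_den == 0 else 100.0 * (tp * tn - fn * fp) / mcc_den,
        "F1": ratio(2 * tp, 2 * tp + fn + fp),
    }


class TestConfusionCounts:
    def test_hand_counted_example(self):
        counts = confusion_counts([1, 1, 0, 0], [1, 0, 0, 1], 1)
        assert (counts.TP, counts.FN, counts.TN, counts.FP) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        y = [1] * 50 + [0] * 50
        counts = confusion_counts(y, y, 1)
        assert (counts.TP, counts.FP, counts.TN, counts.FN) == (50, 0, 50, 0)

    def test_all_positive_predictions_boundary(self):
        counts = confusion_counts([1, 0, 1, 0], [1, 1, 1, 1], 1)
        assert counts.FN == 0 and counts.TN == 0

    def test_length_mismatch(self):
        with pytest.raises(MetricError, match="mismatch"):
            confusion_counts([1, 0], [1], 1)

    def test_sklearn_cross_check(self):
        """Independent tabulation oracle."""
        from sklearn.metrics import confusion_matrix as sk_confusion

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 100)
        y_pred = rng.integers(0, 2, 100)
        counts = confusion_counts(y_true, y_pred, 1)
        tn, fp, fn, tp = sk_confusion(y_true, y_pred).ravel()
        assert (counts.TP, counts.FP, counts.TN, counts.FN) == (tp, fp, tn, fn)


class TestBinaryMetrics:
    def test_perfect_classifier_scores_100(self):
        m = binary_metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
        for value in m.as_dict().values():
            assert value == 100.0

    def test_total_inversion(self):
        m = binary_metrics(ConfusionCounts(TP=0, FP=50, TN=0, FN=50))
        assert m.ACC == 0.0
        assert m.MCC == -100.0
        assert m.F1 == 0.0

    @pytest.mark.parametrize(
        "tp,fn,tn,fp",
        [(45, 5, 48, 2), (99, 1, 100, 0), (10, 0, 0, 5), (7, 3, 2, 8)],
    )
    def test_matches_direct_formula_evaluation(self, tp, fn, tn, fp):
        ours = binary_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)).as_dict()
        expected = _direct_metrics(tp, fn, tn, fp)
        for key, value in expected.items():
            if value is None:
                assert ours[key] is None
            else:
                assert ours[key] == pytest.approx(value, abs=1e-10)

    def test_spot_values_of_derived_example(self):
        m = binary_metrics(ConfusionCounts(TP=45, FP=2, TN=48, FN=5))
        assert m.SEN == pytest.approx(90.00, abs=0.005)
        assert m.SPF == pytest.approx(96.00, abs=0.005)
        assert m.ACC == pytest.approx(93.00, abs=0.005)

    def test_zero_denominators_are_flagged_not_zero(self):
        # no negatives at all: SPF and NPV undefined
        m = binary_metrics(ConfusionCounts(TP=5, FP=0, TN=0, FN=0))
        assert m.SPF is None and m.NPV is None and m.MCC is None
        assert m.SEN == 100.0

    @given(
        tp=st.integers(0, 300), fn=st.integers(0, 300),
        tn=st.integers(0, 300), fp=st.integers(0, 300),
        scale=st.integers(1, 7),
    )
    @settings(max_examples=100, deadline=None)
    def test_ratio_homogeneity(self, tp, fn, tn, fp, scale):
        """Scaling all four counts by an integer leaves every defined
        metric unchanged (the formulas are ratios)."""
        if tp + fn + tn + fp == 0:
            return
        base = binary_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        scaled = binary_metrics(
            ConfusionCounts(TP=tp * scale, FP=fp * scale,
                            TN=tn * scale, FN=fn * scale)
        )
        for key, value in base.as_dict().items():
            other = scaled.as_dict()[key]
            if value is None:
                assert other is None
            else:
                assert other == pytest.approx(value, abs=1e-9)

    @given(
        tp=st.integers(1, 200), fn=st.integers(1, 200),
        tn=st.integers(1, 200), fp=st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_inversion_flips_mcc_and_complements_acc(self, tp, fn, tn, fp):
        m = binary_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        inv = binary_metrics(ConfusionCounts(TP=fn, FP=tn, TN=fp, FN=tp))
        assert inv.MCC == pytest.approx(-m.MCC, abs=1e-9)
        assert inv.ACC == pytest.approx(100.0 - m.ACC, abs=1e-9)


class TestMulticlassMetrics:
    def test_perfect_3class_scores_100_under_both_schemes(self):
        confmat = np.eye(3, dtype=int) * 50
        for scheme in ("macro_ovr", "micro"):
            m = multiclass_metrics(confmat, scheme)
            assert m.ACC == 100.0
            assert m.SEN == 100.0
            assert m.MCC == 100.0

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_uniform_confusion_macro_sen_is_100_over_k(self, k):
        """Closed form: with every cell equal, each class's one-vs-rest
        sensitivity is 1/k, so the macro average is 100/k percent."""
        confmat = np.full((k, k), 10, dtype=int)
        m = multiclass_metrics(confmat, "macro_ovr")
        assert m.SEN == pytest.approx(100.0 / k, abs=1e-9)

    def test_binary_macro_matches_sen_spf_symmetry(self):
        """For K=2 the macro SEN equals (SEN+SPF)/2 of the direct binary
        computation — an algebraic identity of the one-vs-rest collapse."""
        confmat = np.array([[40, 10], [5, 45]])
        direct = binary_metrics(
            ConfusionCounts(TP=45, FN=5, TN=40, FP=10)
        )
        macro = multiclass_metrics(confmat, "macro_ovr")
        assert macro.SEN == pytest.approx((direct.SEN + direct.SPF) / 2, abs=1e-9)
        assert macro.SPF == pytest.approx((direct.SEN + direct.SPF) / 2, abs=1e-9)

    def test_micro_acc_is_trace_over_total(self):
        confmat = np.array([[30, 5, 5], [2, 38, 0], [1, 3, 36]])
        m = multiclass_metrics(confmat, "micro")
        assert m.ACC == pytest.approx(100.0 * confmat.trace() / confmat.sum())

    def test_non_square_rejected(self):
        with pytest.raises(MetricError, match="square"):
            multiclass_metrics(np.ones((2, 3)))

    def test_confusion_matrix_builder(self):
        mat = confusion_matrix([0, 1, 2, 2], [0, 2, 2, 1], 3)
        assert mat[0, 0] == 1 and mat[1, 2] == 1 and mat[2, 2] == 1 and mat[2, 1] == 1
        assert mat.sum() == 4

    def test_dispatch_binary_vs_multiclass(self):
        y_true = [0, 0, 1, 1]
        y_pred = [0, 1, 1, 1]
        m = metrics_from_predictions(y_true, y_pred, 2)
        assert m.SEN == 100.0  # both positives found
        assert m.SPF == 50.0


def _auc_by_concordance(y_true, scores, positive):
    """Brute-force Mann-Whitney probability: concordant pairs / all pairs,
    ties counted half."""
    pos = [s for y, s in zip(y_true, scores) if y == positive]
    neg = [s for y, s in zip(y_true, scores) if y != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_auc_1(self):
        roc = roc_curve_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], 1)
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0.0 and roc.fpr[-1] == 1.0
        assert roc.tpr[0] == 0.0 and roc.tpr[-1] == 1.0

    def test_inverted_scores_auc_0(self):
        roc = roc_curve_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1], 1)
        assert roc.auc == 0.0

    def test_fpr_is_non_decreasing(self):
        rng = np.random.default_rng(1)
        roc = roc_curve_auc(rng.integers(0, 2, 100), rng.normal(size=100), 1)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_single_class_flags_undefined(self):
        roc = roc_curve_auc([1, 1, 1], [0.1, 0.5, 0.9], 1)
        assert roc.auc is None

    @pytest.mark.parametrize("n,tie_fraction", [(50, 0.0), (200, 0.3)])
    def test_auc_equals_concordance_probability(self, n, tie_fraction):
        """Trapezoid AUC must equal the pairwise concordance count,
        including grouped tied scores."""
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, n)
        scores = rng.normal(size=n) + 0.5 * y
        if tie_fraction:
            idx = rng.choice(n, int(tie_fraction * n), replace=False)
            scores[idx] = np.round(scores[idx], 1)  # create ties
        roc = roc_curve_auc(y, scores, 1)
        oracle = _auc_by_concordance(y, scores, 1)
        assert roc.auc == pytest.approx(oracle, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        n = 2000
        y = np.repeat([0, 1], n // 2)
        roc = roc_curve_auc(y, rng.normal(size=n), 1)
        assert roc.auc == pytest.approx(0.5, abs=0.05)


class TestAggregation:
    def test_average_skips_undefined(self):
        a = binary_metrics(ConfusionCounts(TP=5, FP=0, TN=0, FN=0))  # SPF None
        b = binary_metrics(ConfusionCounts(TP=40, FP=10, TN=40, FN=10))
        avg = average_metric_sets([a, b])
        assert avg.SPF == b.SPF  # only the defined fold contributes
        assert avg.SEN == pytest.approx((100.0 + b.SEN) / 2)
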