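"""Confusion-matrix metrics and ROC/AUC for seizure-detection evaluation.

Seven metrics are reported per case and classifier, all in percent:
sensitivity SEN = TP/(TP+FN), specificity SPF = TN/(TN+FP), accuracy
ACC = (TP+TN)/total, positive/negative predictive value PPV = TP/(TP+FP)
and NPV = TN/(TN+FN), Matthews correlation coefficient

    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)),

and F1 = 2TP/(2TP+FN+FP).  A zero denominator marks that metric
undefined (``None``) rather than silently zero, so fold averages are not
corrupted.

Multi-class problems are collapsed one-vs-rest: macro averaging evaluates
each class as positive in turn and averages; micro averaging pools the
one-vs-rest counts (with ACC as trace/total, the standard multi-class
accuracy).  ROC curves and AUC use threshold sweeps with tied scores
grouped; AUC equals the Mann-Whitney concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from math import sqrt

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

METRIC_ORDER = ("ACC", "SPF", "SEN", "PPV", "NPV", "MCC", "F1")


class MetricError(ValueError):
    """Invalid metric input."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion tabulation."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise MetricError("confusion counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise MetricError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    """The seven metrics in percent; ``None`` flags an undefined value."""

    SEN: float | None
    SPF: float | None
    ACC: float | None
    PPV: float | None
    NPV: float | None
    MCC: float | None
    F1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def ordered_values(self) -> list[float | None]:
        """Values in the report column order ACC, SPF, SEN, PPV, NPV, MCC, F1."""
        return [getattr(self, name) for name in METRIC_ORDER]


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, positive_class
) -> ConfusionCounts:
    """Tabulate binary TP/FP/TN/FN relative to ``positive_class``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise MetricError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    pos_true = y_true == positive_class
    pos_pred = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_true & pos_pred)),
        FP=int(np.sum(~pos_true & pos_pred)),
        TN=int(np.sum(~pos_true & ~pos_pred)),
        FN=int(np.sum(pos_true & ~pos_pred)),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def binary_metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate the seven metrics (percent) from binary confusion counts."""
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN
    mcc_den = sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fn) * float(tn + fp)
    )
    return MetricSet(
        SEN=_ratio(tp, tp + fn),
        SPF=_ratio(tn, tn + fp),
        ACC=_ratio(tp + tn, c.total),
        PPV=_ratio(tp, tp + fp),
        NPV=_ratio(tn, tn + fn),
        MCC=None if mcc_den == 0 else 100.0 * (tp * tn - fn * fp) / mcc_den,
        F1=_ratio(2 * tp, 2 * tp + fn + fp),
    )


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise MetricError("length mismatch between y_true and y_pred")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (y_true, y_pred), 1)
    return mat


def _ovr_counts(confmat: np.ndarray, cls: int) -> ConfusionCounts:
    tp = int(confmat[cls, cls])
    fn = int(confmat[cls].sum() - tp)
    fp = int(confmat[:, cls].sum() - tp)
    tn = int(confmat.sum() - tp - fn - fp)
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def multiclass_metrics(confmat: np.ndarray, scheme: str = "macro_ovr") -> MetricSet:
    """Collapse a K x K confusion matrix to one MetricSet.

    ``macro_ovr`` evaluates each class one-vs-rest and averages the
    defined values; ``micro`` pools the one-vs-rest counts (ACC is
    trace/total).  For K = 2 under macro averaging, SEN and SPF are each
    the mean of the two per-class one-vs-rest values.
    """
    confmat = np.asarray(confmat)
    if confmat.ndim != 2 or confmat.shape[0] != confmat.shape[1]:
        raise MetricError("confusion matrix must be square")
    k = confmat.shape[0]
    if k < 2:
        raise MetricError("need at least 2 classes")
    if scheme == "macro_ovr":
        per_class = [binary_metrics(_ovr_counts(confmat, c)) for c in range(k)]
        return MetricSet(
            **{
                f.name: _mean_defined([getattr(m, f.name) for m in per_class])
                for f in fields(MetricSet)
            }
        )
    if scheme == "micro":
        pooled = [_ovr_counts(confmat, c) for c in range(k)]
        counts = ConfusionCounts(
            TP=sum(c.TP for c in pooled),
            FP=sum(c.FP for c in pooled),
            TN=sum(c.TN for c in pooled),
            FN=sum(c.FN for c in pooled),
        )
        metrics = binary_metrics(counts)
        total = confmat.sum()
        acc = _ratio(np.trace(confmat), total)
        return MetricSet(
            SEN=metrics.SEN, SPF=metrics.SPF, ACC=acc,
            PPV=metrics.PPV, NPV=metrics.NPV, MCC=metrics.MCC, F1=metrics.F1,
        )
    raise MetricError(f"unknown scheme {scheme!r}; use 'macro_ovr' or 'micro'")


def metrics_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    n_classes: int,
    *,
    positive_class: int = 1,
    scheme: str = "macro_ovr",
) -> MetricSet:
    """Binary problems use the direct formulas with class 1 positive by
    default; multi-class problems collapse one-vs-rest per ``scheme``."""
    if n_classes == 2:
        return binary_metrics(confusion_counts(y_true, y_pred, positive_class))
    return multiclass_metrics(confusion_matrix(y_true, y_pred, n_classes), scheme)


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC curve; ``auc`` is None when undefined."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float | None

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr}).to_csv(path, index=False)


def roc_curve_auc(
    y_true: np.ndarray, scores: np.ndarray, positive_class
) -> ROCCurve:
    """ROC from real-valued scores (higher = more positive) and trapezoid AUC.

    Tied scores collapse into a single threshold step.  If ``y_true``
    contains only one class the AUC is undefined and flagged ``None``
    with a degenerate two-point curve.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise MetricError("length mismatch between y_true and scores")
    is_pos = y_true == positive_class
    if is_pos.all() or (~is_pos).all():
        return ROCCurve(
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, -np.inf]),
            auc=None,
        )
    fpr, tpr, thresholds = _sk_roc_curve(
        is_pos.astype(int), scores, drop_intermediate=False
    )
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds,
                    auc=float(_sk_auc(fpr, tpr)))


def average_metric_sets(metric_sets: list[MetricSet]) -> MetricSet:
    """Fold-average: per metric, the mean over folds where it is defined."""
    return MetricSet(
        **{
            f.name: _mean_defined([getattr(m, f.name) for m in metric_sets])
            for f in fields(MetricSet)
        }
    )
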