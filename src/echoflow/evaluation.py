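"""Confusion matrices, detection metrics, ROC/AUC, multi-view label fusion,
and fold aggregation.

Conventions
-----------
* The abnormal class (RWMA) is the positive class.
* All rate metrics are percentages in [0, 100]; AUC is returned as a
  fraction in [0, 1] (multiply by 100 to compare with printed percentages).
* Metrics with a zero denominator are reported as NaN with a warning rather
  than silently coerced to 0, and fold aggregation ignores NaNs.
* Internal arithmetic is full precision; ``round2`` applies half-up rounding
  to two decimals at reporting time only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "ViewLabelPair",
    "confusion",
    "metrics",
    "roc_auc",
    "fuse_view_labels",
    "aggregate_folds",
    "round2",
]

POSITIVE = "RWMA"
NEGATIVE = "non-RWMA"


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (so 86.265 -> 86.27, not banker's 86.26)."""
    if not np.isfinite(x):
        return float("nan")
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricReport:
    """Percentage metrics of one confusion matrix (NaN where undefined)."""

    sensitivity: float
    fpr: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    auc: float = float("nan")  # fraction in [0, 1] when set

    def rounded(self) -> dict[str, float]:
        return {f.name: round2(getattr(self, f.name)) for f in fields(self)}


def confusion(y_true, y_pred, positive: str = POSITIVE) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with the abnormal class as positive."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"label lengths differ: {len(y_true)} vs {len(y_pred)}")
    t = np.asarray([y == positive for y in y_true])
    p = np.asarray([y == positive for y in y_pred])
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity, FPR, specificity, precision, F1 and accuracy of one matrix.

    TPR = TP/(TP+FN); FPR = FP/(FP+TN); SPE = TN/(TN+FP); P = TP/(TP+FP);
    F1 = 2TP/(2TP+FP+FN); ACC = (TP+TN)/(TP+TN+FP+FN) — each as a percentage.
    """
    return MetricReport(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        fpr=_ratio(cm.fp, cm.fp + cm.tn, "FPR"),
        specificity=_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        precision=_ratio(cm.tp, cm.tp + cm.fp, "precision"),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "F1"),
        accuracy=_ratio(cm.tp + cm.tn, cm.total, "accuracy"),
    )


def roc_auc(scores, y_true, positive: str = POSITIVE):
    """ROC curve and its area.

    AUC equals the probability that a random positive outscores a random
    negative, with ties counted as one half (the rank-statistic definition,
    computed by trapezoidal integration of the ROC curve over all score
    thresholds).  Returns ``(auc, fpr_points, tpr_points)`` with AUC as a
    fraction in [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    t = np.asarray([y == positive for y in y_true])
    if t.all() or not t.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(t.astype(int), scores)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


@dataclass(frozen=True)
class ViewLabelPair:
    """Per-view MI labels of one subject and the fused subject label."""

    a4c_label: str  # "MI" or "non-MI"
    a2c_label: str

    @property
    def fused_label(self) -> str:
        return POSITIVE if "MI" in (self.a4c_label, self.a2c_label) else NEGATIVE


def fuse_view_labels(pairs) -> tuple[list[str], dict[str, int]]:
    """OR-fusion: a subject is RWMA if either view is labelled MI."""
    fused = [p.fused_label for p in pairs]
    counts = {POSITIVE: fused.count(POSITIVE), NEGATIVE: fused.count(NEGATIVE)}
    return fused, counts


def aggregate_folds(reports: list[MetricReport]) -> dict[str, dict[str, float]]:
    """Element-wise max/mean/min of per-fold metrics.

    NaN fold values (undefined metrics) are skipped; a metric that is NaN in
    every fold — e.g. AUC when it was never computed — is omitted entirely.
    """
    if not reports:
        raise ValueError("need at least one fold report")
    out: dict[str, dict[str, float]] = {}
    for f in fields(MetricReport):
        vals = np.asarray([getattr(r, f.name) for r in reports], dtype=float)
        if not np.isfinite(vals).any():
            continue
        out[f.name] = {
            "max": float(np.nanmax(vals)),
            "mean": float(np.nanmean(vals)),
            "min": float(np.nanmin(vals)),
        }
    return out
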