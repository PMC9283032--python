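"""Confusion-matrix metrics in the reporting convention of multitissue
classification benchmarks: per-class precision/recall/F1 plus macro
averages, where the reported "average F1" is the harmonic mean of the
macro-averaged precision and recall (not the mean of per-class F1 scores).
Both conventions are computed; values are rounded to 4 decimals in report
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "per_class_prf",
    "macro_summary",
    "classification_report",
]


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    undefined_precision: np.ndarray  # classes with zero predictions
    undefined_recall: np.ndarray     # classes with zero support
    average_precision: float
    average_recall: float
    average_f1: float                # harmonic mean of the macro averages
    mean_f1: float                   # plain mean of per-class F1 (alt convention)


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.bincount(y_true * n_classes + y_pred,
                         minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


def per_class_prf(cm: ConfusionMatrix):
    """Per-class precision, recall, F1, with flags for the undefined cases
    (zero predictions / zero support), which are reported as 0."""
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    pred_tot = counts.sum(axis=0).astype(float)
    true_tot = counts.sum(axis=1).astype(float)
    undef_p = pred_tot == 0
    undef_r = true_tot == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(undef_p, 0.0, tp / np.where(undef_p, 1, pred_tot))
        recall = np.where(undef_r, 0.0, tp / np.where(undef_r, 1, true_tot))
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return precision, recall, f1, undef_p, undef_r


def macro_summary(precision, recall, f1=None, ndigits: int = 4):
    """Macro averages: unweighted means of per-class precision and recall,
    and their harmonic mean as the reported average F1."""
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    if precision.size < 1:
        raise ValueError("need at least one class")
    ap = float(precision.mean())
    ar = float(recall.mean())
    af1 = 2 * ap * ar / (ap + ar) if (ap + ar) > 0 else 0.0
    return round(ap, ndigits), round(ar, ndigits), round(af1, ndigits)


def classification_report(y_true, y_pred, n_classes: int) -> MetricsReport:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    precision, recall, f1, undef_p, undef_r = per_class_prf(cm)
    ap, ar, af1 = macro_summary(precision, recall)
    return MetricsReport(
        precision=precision, recall=recall, f1=f1,
        undefined_precision=undef_p, undefined_recall=undef_r,
        average_precision=ap, average_recall=ar, average_f1=af1,
        mean_f1=round(float(f1.mean()), 4),
    )
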