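"""Multiclass confusion-matrix metrics: per-class one-vs-rest counts,
sensitivity (MSN) and specificity (MSP), plus macro summaries.

Orientation convention: rows index the actual class, columns the predicted
class, so FN_i is the i-th row sum minus the diagonal (missed actuals) and
FP_i the i-th column sum minus the diagonal.  Ratios with a zero
denominator (a class absent from the data or never predicted) are reported
as NaN with a ``defined`` flag rather than coerced to 0, so macro averages
are taken over defined classes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "PerClassCounts",
    "ClassMetrics",
    "confusion_matrix",
    "per_class_counts",
    "sensitivity_specificity",
    "summary_metrics",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; ``counts[i, j]`` = actual class i predicted as j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")


@dataclass(frozen=True)
class PerClassCounts:
    """One-vs-rest TP/FP/FN/TN per class; each row sums to the grand total."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class sensitivity/specificity (NaN where undefined) + macro summaries."""

    sensitivity: np.ndarray       # MSN_i = TP / (TP + FN)
    specificity: np.ndarray       # MSP_i = TN / (TN + FP)
    sensitivity_defined: np.ndarray
    specificity_defined: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float

    def to_dict(self) -> dict:
        return {
            "sensitivity": [None if not d else float(v) for v, d in
                            zip(self.sensitivity, self.sensitivity_defined)],
            "specificity": [None if not d else float(v) for v, d in
                            zip(self.specificity, self.specificity_defined)],
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
        }


def confusion_matrix(y_true, y_pred, K: int) -> ConfusionMatrix:
    """Count actual-vs-predicted pairs into a K x K matrix."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if len(y_true) and (
        y_true.min() < 0 or y_true.max() >= K or y_pred.min() < 0 or y_pred.max() >= K
    ):
        raise ValueError(f"class ids must lie in [0, {K})")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def per_class_counts(cm: ConfusionMatrix) -> PerClassCounts:
    """One-vs-rest counts: TP_i = C[i,i]; FN_i = row_i - TP_i;
    FP_i = col_i - TP_i; TN_i = total - TP_i - FN_i - FP_i."""
    c = cm.counts
    tp = np.diag(c).copy()
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = cm.total - tp - fn - fp
    return PerClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_ratio(num: np.ndarray, den: np.ndarray):
    defined = den > 0
    out = np.full(len(num), np.nan)
    out[defined] = num[defined] / den[defined]
    return out, defined


def sensitivity_specificity(counts: PerClassCounts) -> tuple[np.ndarray, np.ndarray,
                                                             np.ndarray, np.ndarray]:
    """MSN_i and MSP_i with their defined-flags (NaN where denominator is 0)."""
    msn, msn_def = _safe_ratio(counts.tp, counts.tp + counts.fn)
    msp, msp_def = _safe_ratio(counts.tn, counts.tn + counts.fp)
    return msn, msp, msn_def, msp_def


def summary_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Accuracy (trace/total) and macro precision/recall over defined classes."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = per_class_counts(cm)
    msn, msp, msn_def, msp_def = sensitivity_specificity(counts)
    precision, prec_def = _safe_ratio(counts.tp, counts.tp + counts.fp)
    accuracy = float(np.trace(cm.counts) / cm.total)
    macro_precision = float(np.mean(precision[prec_def])) if prec_def.any() else float("nan")
    macro_recall = float(np.mean(msn[msn_def])) if msn_def.any() else float("nan")
    return ClassMetrics(
        sensitivity=msn,
        specificity=msp,
        sensitivity_defined=msn_def,
        specificity_defined=msp_def,
        accuracy=accuracy,
        macro_precision=macro_precision,
        macro_recall=macro_recall,
    )
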