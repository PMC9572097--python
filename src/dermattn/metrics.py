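"""Multiclass confusion-matrix decomposition and evaluation metrics.

The confusion matrix A is oriented rows = true class, columns = predicted
class.  Per-class one-vs-rest counts follow from it directly:

    TP_c = a_cc          FP_c = column sum - TP_c
    FN_c = row sum - TP_c        TN_c = total - TP_c - FP_c - FN_c

and the derived metrics are sensitivity (recall) TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 as the harmonic mean of precision and
recall, overall accuracy ΣTP/total, and balanced accuracy as the mean of
per-class (sensitivity+specificity)/2.  Macro metrics are unweighted class
means, which makes them sensitive to minority-class performance.  One-vs-rest
ROC AUC is computed with the Mann-Whitney rank statistic (equivalent to
trapezoidal integration of the ROC curve, with tie correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "confusion_matrix",
    "per_class_counts",
    "metric_report",
    "roc_auc_ovr",
    "PerClassCounts",
    "MetricsReport",
]


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """C×C integer matrix with a_ij = #{samples with true class i predicted j}."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (t, p), 1)
    return mat


@dataclass
class PerClassCounts:
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray


def per_class_counts(mat: np.ndarray) -> PerClassCounts:
    """Decompose a confusion matrix into per-class one-vs-rest TP/FP/FN/TN."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or np.any(mat < 0):
        raise ValueError("confusion matrix must be square and non-negative")
    tp = np.diag(mat).astype(np.int64)
    fp = mat.sum(axis=0) - tp
    fn = mat.sum(axis=1) - tp
    tn = mat.sum() - tp - fp - fn
    return PerClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_div(num: np.ndarray, den: np.ndarray, flags: list[str], name: str) -> np.ndarray:
    num = num.astype(np.float64)
    den = den.astype(np.float64)
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        flags.append(f"{name}: zero denominator for classes {np.flatnonzero(~ok).tolist()}, reported 0")
    return out


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics; all values in [0, 1]."""

    confusion: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    accuracy: float
    balanced_accuracy: float
    macro_sensitivity: float
    macro_precision: float
    macro_f1: float
    auc: np.ndarray | None = None
    macro_auc: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "precision": self.precision.tolist(),
            "f1": self.f1.tolist(),
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "warnings": list(self.warnings),
        }
        if self.auc is not None:
            d["auc"] = self.auc.tolist()
            d["macro_auc"] = self.macro_auc
        return d

    def save_confusion_csv(self, path) -> None:
        np.savetxt(path, self.confusion, fmt="%d", delimiter=",")


def metric_report(mat: np.ndarray, scores: np.ndarray | None = None,
                  true_labels=None, f1_includes_tn: bool = False) -> MetricsReport:
    """Compute the full metric set from a confusion matrix.

    Parameters
    ----------
    mat : C×C confusion matrix (rows true, columns predicted).
    scores : optional (N, C) probability matrix; when given together with
        ``true_labels``, per-class and macro one-vs-rest AUC are included.
    f1_includes_tn : compatibility flag that adds TN to the F1 denominator
        (a non-standard variant some reports print); the default is the
        harmonic mean of precision and recall.
    """
    counts = per_class_counts(mat)
    total = int(np.asarray(mat).sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    flags: list[str] = []
    sens = _safe_div(counts.tp, counts.tp + counts.fn, flags, "sensitivity")
    spec = _safe_div(counts.tn, counts.tn + counts.fp, flags, "specificity")
    prec = _safe_div(counts.tp, counts.tp + counts.fp, flags, "precision")
    denom = 2 * counts.tp + counts.fp + counts.fn
    if f1_includes_tn:
        denom = denom + counts.tn
    f1 = _safe_div(2 * counts.tp, denom, flags, "f1")
    acc = float(counts.tp.sum()) / total
    bal_acc = float(np.mean((sens + spec) / 2.0))

    auc = macro_auc = None
    if scores is not None:
        if true_labels is None:
            raise ValueError("true_labels are required to compute AUC from scores")
        auc, macro_auc = roc_auc_ovr(true_labels, scores)

    return MetricsReport(
        confusion=np.asarray(mat),
        sensitivity=sens, specificity=spec, precision=prec, f1=f1,
        accuracy=acc, balanced_accuracy=bal_acc,
        macro_sensitivity=float(sens.mean()),
        macro_precision=float(prec.mean()),
        macro_f1=float(f1.mean()),
        auc=auc, macro_auc=macro_auc, warnings=flags,
    )


def roc_auc_ovr(true_labels, scores) -> tuple[np.ndarray, float]:
    """One-vs-rest ROC AUC per class via the Mann-Whitney rank statistic.

    For class c with n₁ positives and n₀ negatives,
    AUC_c = (Σ ranks of positives − n₁(n₁+1)/2) / (n₁ n₀), using average
    ranks for ties — identical to trapezoidal ROC integration.
    """
    t = np.asarray(true_labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] != t.shape[0]:
        raise ValueError("scores must be (N, C) aligned with true_labels")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n, c = s.shape
    aucs = np.empty(c)
    for k in range(c):
        pos = t == k
        n1 = int(pos.sum())
        n0 = n - n1
        if n1 == 0 or n0 == 0:
            raise ValueError(f"AUC undefined for class {k}: needs >=1 positive and >=1 negative")
        ranks = rankdata(s[:, k])
        aucs[k] = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return aucs, float(aucs.mean())
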