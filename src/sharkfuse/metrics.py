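"""Evaluation statistics: confusion matrix, one-vs-rest binary metrics,
ROC/AUC by the trapezoid rule, and bootstrap confidence intervals.

The K-class task is reduced one-vs-rest: for each class k, TP is the
diagonal entry, FN the rest of row k, FP the rest of column k, TN the
remainder.  Headline precision / sensitivity / specificity / F1 / AUC are
unweighted (macro) means over classes; headline accuracy is the pooled
fraction correct, trace(confusion)/N.  Any 0/0 metric denominator yields 0
with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "ROCCurve",
    "MetricsReport",
    "confusion_matrix",
    "one_vs_rest_counts",
    "binary_metrics",
    "roc_curve",
    "auc_trapezoid",
    "full_report",
    "accuracy_confidence_interval",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K); [i, j] = true class i predicted as j
    class_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass(frozen=True)
class ROCCurve:
    points: np.ndarray  # (n_points, 2) of (FPR, TPR), from (0,0) to (1,1)
    thresholds: np.ndarray


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    per_class: dict[str, dict[str, float]]
    confusion: ConfusionMatrix
    averaging: str = "macro one-vs-rest (accuracy pooled)"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
            "averaging": self.averaging,
            "per_class": self.per_class,
            "confusion": self.confusion.counts.tolist(),
            "class_names": list(self.confusion.class_names),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)


def confusion_matrix(y_true, y_pred, n_classes: int, class_names=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains indices outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    if class_names is None:
        class_names = tuple(f"class_{k}" for k in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def one_vs_rest_counts(cm: ConfusionMatrix, class_index: int) -> BinaryCounts:
    k = class_index
    c = cm.counts
    if not 0 <= k < c.shape[0]:
        raise ValueError(f"class_index {k} out of range for {c.shape[0]} classes")
    tp = int(c[k, k])
    fn = int(c[k].sum() - tp)
    fp = int(c[:, k].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s; reporting 0", what)
        return 0.0
    return num / den


def binary_metrics(c: BinaryCounts) -> dict[str, float]:
    """Accuracy, precision, sensitivity (recall/TPR), specificity, F1."""
    n = c.tp + c.tn + c.fp + c.fn
    acc = _safe_div(c.tp + c.tn, n, "accuracy")
    prec = _safe_div(c.tp, c.tp + c.fp, "precision")
    sens = _safe_div(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_div(c.tn, c.tn + c.fp, "specificity")
    f1 = _safe_div(2 * prec * sens, prec + sens, "f1")
    return {
        "accuracy": acc,
        "precision": prec,
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
    }


def roc_curve(scores, labels) -> ROCCurve:
    """Threshold sweep over descending distinct scores; binary labels.

    At threshold t a sample is called positive when score >= t.  Points run
    from (0, 0) (t = +inf) to (1, 1) (t = min score), non-decreasing in both
    coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve needs at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]  # last index of each tie block
    tps = np.cumsum(y == 1)[distinct]
    fps = np.cumsum(y == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return ROCCurve(points=np.column_stack([fpr, tpr]), thresholds=thresholds)


def auc_trapezoid(curve: ROCCurve) -> float:
    """Sum of (FPR_{i+1}-FPR_i) * (TPR_i+TPR_{i+1})/2 over the curve."""
    fpr, tpr = curve.points[:, 0], curve.points[:, 1]
    return float(np.sum(np.diff(fpr) * (tpr[:-1] + tpr[1:]) / 2.0))


def full_report(
    p_ensemble: np.ndarray, labels, class_names=None
) -> MetricsReport:
    """Per-class one-vs-rest metrics (scores = class probability column),
    macro-averaged headline values, pooled headline accuracy."""
    p = np.asarray(p_ensemble, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, k = p.shape
    if class_names is None:
        class_names = tuple(f"class_{i}" for i in range(k))
    preds = p.argmax(axis=1)
    cm = confusion_matrix(labels, preds, k, class_names)
    per_class: dict[str, dict[str, float]] = {}
    for i, name in enumerate(class_names):
        stats = binary_metrics(one_vs_rest_counts(cm, i))
        stats["auc"] = auc_trapezoid(roc_curve(p[:, i], (labels == i).astype(int)))
        per_class[name] = stats
    macro = {
        m: float(np.mean([per_class[c][m] for c in class_names]))
        for m in ("precision", "sensitivity", "specificity", "f1", "auc")
    }
    return MetricsReport(
        accuracy=float(np.trace(cm.counts) / n),
        precision=macro["precision"],
        sensitivity=macro["sensitivity"],
        specificity=macro["specificity"],
        f1=macro["f1"],
        auc=macro["auc"],
        per_class=per_class,
        confusion=cm,
    )


def plot_roc_curves(p_ensemble: np.ndarray, labels, class_names, path) -> None:
    """One-vs-rest ROC curves (one per class) with the chance diagonal.

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(p_ensemble, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fig, ax = plt.subplots(figsize=(5, 5))
    for i, name in enumerate(class_names):
        curve = roc_curve(p[:, i], (labels == i).astype(int))
        auc = auc_trapezoid(curve)
        ax.plot(curve.points[:, 0], curve.points[:, 1], label=f"{name} (AUC {auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def accuracy_confidence_interval(
    correct_flags, n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """Seeded percentile bootstrap over resampled mean accuracy."""
    flags = np.asarray(correct_flags, dtype=float)
    if flags.size < 1:
        raise ValueError("need at least one flag")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rng = np.random.default_rng(seed)
    means = rng.choice(flags, size=(n_boot, flags.size), replace=True).mean(axis=1)
    lo = float(np.quantile(means, alpha / 2))
    hi = float(np.quantile(means, 1 - alpha / 2))
    point = float(flags.mean())
    return (min(lo, point), max(hi, point))
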