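"""Evaluation metrics: confusion-count statistics, threshold curves, R².

All confusion-count metrics follow the textbook formulas; zero denominators
return 0.0 and set a warning flag instead of raising, so that aggregation
over many evaluation folds never drops a fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_from_scores",
    "binary_metrics",
    "threshold_curves",
    "r_squared",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold probability scores at ``threshold`` and count outcomes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (labels == 1))),
        tn=int(np.sum((pred == 0) & (labels == 0))),
        fp=int(np.sum((pred == 1) & (labels == 0))),
        fn=int(np.sum((pred == 0) & (labels == 1))),
    )


def binary_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, precision, F1 and MCC.

    Recall is sensitivity. Ratios with a zero denominator are reported as
    0.0 and the metric name is listed under ``"degenerate"``; a warning is
    emitted so the condition is never silent.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    flags: list[str] = []
    sensitivity = _safe_div(tp, tp + fn, flags, "sensitivity")
    specificity = _safe_div(tn, tn + fp, flags, "specificity")
    accuracy = (tp + tn) / c.total
    precision = _safe_div(tp, tp + fp, flags, "precision")
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, flags, "f1")
    mcc_den = np.sqrt(float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, flags, "mcc")
    if flags:
        warnings.warn(f"zero-denominator metrics reported as 0: {flags}", stacklevel=2)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "precision": precision,
        "f1": f1,
        "mcc": mcc,
        "degenerate": flags,
    }


def _roc_pr_points(scores: np.ndarray, labels: np.ndarray):
    """Score-sorted cumulative counts; tied scores cross thresholds together."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # indices where the score strictly drops: threshold boundaries
    distinct = np.where(np.diff(s) < 0)[0]
    boundaries = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y)[boundaries].astype(float)
    fps = (boundaries + 1) - tps
    return tps, fps


def threshold_curves(scores, labels, pr_integration: str = "trapezoid") -> dict:
    """ROC and precision-recall curves with their summary areas.

    Returns ``roc_auc`` (trapezoidal), ``aupr`` (PR area, trapezoidal by
    default or step-wise with ``pr_integration="step"``), ``aps``
    (step-wise average precision), and the raw curve coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute threshold curves")
    if pr_integration not in ("trapezoid", "step"):
        raise ValueError(f"unknown pr_integration: {pr_integration!r}")

    tps, fps = _roc_pr_points(scores, labels)
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    roc_auc = float(np.trapezoid(tpr, fpr))

    precision = tps / (tps + fps)
    recall = tps / n_pos
    # prepend the (recall=0, precision=first) anchor
    precision_full = np.r_[precision[0], precision]
    recall_full = np.r_[0.0, recall]

    if pr_integration == "trapezoid":
        aupr = float(np.trapezoid(precision_full, recall_full))
    else:
        aupr = float(np.sum(np.diff(recall_full) * precision))
    aps = float(np.sum(np.diff(recall_full) * precision))

    return {
        "roc_auc": roc_auc,
        "aupr": aupr,
        "aps": aps,
        "roc_curve": (fpr, tpr),
        "pr_curve": (recall_full, precision_full),
    }


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination: 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between y_true and y_pred")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant; R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot
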