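"""Confusion-matrix evaluation metrics: accuracy, F1 and G-mean.

G-mean — the geometric mean of sensitivity TP/(TP+FN) and specificity
TN/(TN+FP) — complements accuracy and F1 under class imbalance: a
classifier that ignores the minority class scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "compute_metrics", "macro_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        t = y_true == positive
        p = y_pred == positive
        return cls(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, F1 and G-mean of a binary confusion matrix.

    accuracy = (TP+TN)/(TP+FP+TN+FN); F1 = 2TP/(2TP+FP+FN);
    G-mean = sqrt( TP/(TP+FN) * TN/(TN+FP) ).  Undefined ratios
    (zero denominators) are reported as 0 with ``degenerate=True``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    degenerate = False
    accuracy = (cm.tp + cm.tn) / cm.total

    f1_den = 2 * cm.tp + cm.fp + cm.fn
    if f1_den == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * cm.tp / f1_den

    pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
    if pos == 0 or neg == 0:
        g_mean, degenerate = 0.0, True
    else:
        g_mean = float(np.sqrt((cm.tp / pos) * (cm.tn / neg)))

    return {"accuracy": accuracy, "f1": f1, "g_mean": g_mean,
            "degenerate": degenerate}


def macro_metrics(y_true, y_pred, classes=None) -> dict:
    """Macro-averaged one-vs-rest metrics for multi-class labels.

    Accuracy is the plain multi-class fraction correct; F1 and G-mean
    are averaged over the per-class one-vs-rest confusion matrices.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(y_true)
    per_class = [
        compute_metrics(ConfusionMatrix.from_predictions(y_true, y_pred, c))
        for c in classes
    ]
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "f1": float(np.mean([m["f1"] for m in per_class])),
        "g_mean": float(np.mean([m["g_mean"] for m in per_class])),
        "degenerate": any(m["degenerate"] for m in per_class),
    }
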