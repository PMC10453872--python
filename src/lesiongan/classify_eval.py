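"""Discriminator-as-classifier prediction and the evaluation stack.

The trained discriminator's real-class probabilities (benign, malignant —
renormalized to exclude the fake class) give both hard labels and a
malignancy score per image. Metrics follow the usual confusion-matrix
definitions with malignant as the positive class; the balanced accuracy
score (BAS) is the mean of recall (sensitivity) and specificity, and the
ROC/AUC summarize the score's ranking quality across thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .gan_core.nets import DiscriminatorNet

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "predict",
    "confusion",
    "classification_metrics",
    "roc_auc",
    "evaluate",
]

POSITIVE_CLASS = 1  # malignant


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts, malignant = positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Confusion-derived metrics (percentages) plus optional ROC/AUC.

    ``degenerate`` lists metrics whose denominator was zero; those are
    reported as 0 rather than raising, so batch evaluation stays total.
    """

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    bas: float
    auc: float | None = None
    roc_points: list | None = None
    degenerate: list = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "bas": self.bas,
            "auc": self.auc,
            "degenerate": self.degenerate,
        }
        return json.dumps(d)


def predict(D: DiscriminatorNet, images: np.ndarray, batch: int = 64):
    """Labels and malignancy scores for a batch of 64×64×3 images in [−1,1].

    The two real-class probabilities are renormalized (the fake class is
    excluded); the label is their argmax and the score the renormalized
    malignant probability, so ``label == 1`` iff ``score ≥ 0.5``.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError("images must be a 4-D array")
    if x.shape[1:] == (64, 64, 3):
        x = x.transpose(0, 3, 1, 2)
    labels = np.empty(x.shape[0], dtype=np.intp)
    scores = np.empty(x.shape[0])
    for i in range(0, x.shape[0], batch):
        probs = D.forward(x[i : i + batch], train=False)
        cls = D.class_probs(probs)
        labels[i : i + batch] = np.argmax(cls, axis=1)
        scores[i : i + batch] = cls[:, POSITIVE_CLASS]
    return labels, scores


def confusion(labels_true, labels_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with malignant (1) as the positive class."""
    yt = np.asarray(labels_true)
    yp = np.asarray(labels_pred)
    if yt.shape != yp.shape:
        raise ValueError("label arrays must have equal length")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be 0 (benign) or 1 (malignant)")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return ConfusionMatrix(tp, tn, fp, fn)


def _ratio(num: int, den: int, name: str, degenerate: list) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, specificity, F1, BAS — as percentages."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    deg: list = []
    accuracy = (cm.tp + cm.tn) / cm.n
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", deg)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", deg)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", deg)
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        deg.append("f1")
        f1 = 0.0
    bas = (recall + specificity) / 2
    return MetricsReport(
        accuracy=100 * accuracy,
        precision=100 * precision,
        recall=100 * recall,
        specificity=100 * specificity,
        f1=100 * f1,
        bas=100 * bas,
        degenerate=deg,
    )


def roc_auc(labels_true, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) by threshold sweep + trapezoidal AUC.

    Tied scores fall into the same threshold step, which makes the
    trapezoidal area equal the pairwise probability-of-correct-ranking
    with ties counted ½.
    """
    yt = np.asarray(labels_true)
    s = np.asarray(scores, dtype=np.float64)
    if yt.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if np.unique(yt).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(yt, s, pos_label=POSITIVE_CLASS)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def evaluate(
    D: DiscriminatorNet,
    images: np.ndarray,
    labels_true: np.ndarray,
    out_json: str | Path | None = None,
) -> MetricsReport:
    """Predict, score, and compile the full metrics report for a test set."""
    pred, scores = predict(D, images)
    cm = confusion(labels_true, pred)
    report = classification_metrics(cm)
    try:
        report.roc_points, report.auc = roc_auc(labels_true, scores)
    except ValueError:
        report.degenerate.append("auc")
    if out_json is not None:
        Path(out_json).write_text(report.to_json())
    return report
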