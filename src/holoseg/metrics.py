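"""Segmentation and classification evaluation.

Segmentation quality against a ground-truth mask is summarised by four
similarity measures: sensitivity TP/(TP+FN), specificity TN/(TN+FP), Dice
2TP/(2TP+FP+FN), and the symmetric Hausdorff distance between boundary point
sets (Euclidean, pixel units). Classification is summarised by accuracy (%)
and its complement, the loss (%), with a full confusion table over the four
classes plus `unclassified`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contours import boundary_pixels
from .errors import DegenerateInputError, ParameterError
from .imaging import CLASS_LABELS, UNCLASSIFIED, BinaryMask


@dataclass
class ConfusionCounts:
    """Pixel (or sample) counts of a binary prediction against truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SegMetrics:
    sensitivity: float
    specificity: float
    dice: float
    hausdorff: float


@dataclass
class ClassificationReport:
    accuracy_pct: float
    loss_pct: float
    per_class_confusion: pd.DataFrame


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Pixelwise TP/FP/TN/FN counts, positive = cell."""
    if pred.shape != truth.shape:
        raise ParameterError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p = pred.pixels.astype(bool)
    t = truth.pixels.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)), fn=int(np.sum(~p & t)))


def sensitivity(c: ConfusionCounts) -> float:
    """True positive rate TP/(TP+FN)."""
    if c.tp + c.fn == 0:
        raise DegenerateInputError("sensitivity undefined: no positive truth pixels")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """True negative rate TN/(TN+FP)."""
    if c.tn + c.fp == 0:
        raise DegenerateInputError("specificity undefined: no negative truth pixels")
    return c.tn / (c.tn + c.fp)


def dice(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN)."""
    if c.tp + c.fp + c.fn == 0:
        raise DegenerateInputError("Dice undefined: both masks empty")
    return 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)


def hausdorff(g: np.ndarray, s: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (Euclidean, pixels)."""
    g = np.atleast_2d(np.asarray(g, dtype=np.float64))
    s = np.atleast_2d(np.asarray(s, dtype=np.float64))
    if g.size == 0 or s.size == 0:
        raise ParameterError("Hausdorff distance needs two nonempty point sets")
    d_gs = cKDTree(s).query(g)[0].max()
    d_sg = cKDTree(g).query(s)[0].max()
    return float(max(d_gs, d_sg))


def seg_metrics(pred: BinaryMask, truth: BinaryMask,
                hausdorff_on: str = "boundary") -> SegMetrics:
    """All four similarity measures for one predicted/truth mask pair.

    The Hausdorff distance is taken between boundary pixel sets by default
    (a contour-error measure); hausdorff_on="mask" compares the filled masks.
    """
    c = confusion(pred, truth)
    if hausdorff_on == "boundary":
        g = boundary_pixels(truth)
        s = boundary_pixels(pred)
    elif hausdorff_on == "mask":
        g = np.argwhere(truth.pixels > 0)
        s = np.argwhere(pred.pixels > 0)
    else:
        raise ParameterError(f"unknown hausdorff_on {hausdorff_on!r}")
    return SegMetrics(sensitivity=sensitivity(c), specificity=specificity(c),
                      dice=dice(c), hausdorff=hausdorff(g, s))


def aggregate_seg_metrics(metrics: Iterable[SegMetrics]) -> Dict[str, Dict[str, float]]:
    """Mean +/- standard deviation of each measure over a dataset."""
    rows = list(metrics)
    if not rows:
        raise ParameterError("no metrics to aggregate")
    out = {}
    for name in ("sensitivity", "specificity", "dice", "hausdorff"):
        vals = np.array([getattr(m, name) for m in rows])
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out


def accuracy_and_loss(pred: Sequence[str], truth: Sequence[str]) -> ClassificationReport:
    """Accuracy (%) and loss = 100 - accuracy, with a 5x5 confusion table.

    `unclassified` predictions count as incorrect.
    """
    if len(pred) != len(truth):
        raise ParameterError("prediction and truth lists differ in length")
    if not pred:
        raise ParameterError("empty prediction list")
    labels: List[str] = list(CLASS_LABELS) + [UNCLASSIFIED]
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    correct = 0
    for p, t in zip(pred, truth):
        if p not in labels or t not in labels:
            raise ParameterError(f"unknown label in report: {p!r} / {t!r}")
        table.loc[t, p] += 1
        if p == t and p != UNCLASSIFIED:
            correct += 1
    acc = 100.0 * correct / len(pred)
    return ClassificationReport(accuracy_pct=acc, loss_pct=100.0 - acc,
                                per_class_confusion=table)
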