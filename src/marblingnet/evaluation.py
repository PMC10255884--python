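"""Segmentation metrics from micro-aggregated confusion totals.

The four metrics (IoU, precision, recall, F1) are computed from pixel
counts pooled over the whole validation set — not averaged per image —
with class 1 (marbling) as the positive class:

    IoU       = TP / (TP + FN + FP)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionTotals", "confusion_totals", "iou", "precision",
           "recall", "f1", "all_metrics"]


@dataclass
class ConfusionTotals:
    """Pixel counts aggregated over all evaluated images."""
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionTotals") -> "ConfusionTotals":
        return ConfusionTotals(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_totals(predictions: Sequence[np.ndarray],
                     references: Sequence[np.ndarray]) -> ConfusionTotals:
    """Pixel-wise confusion totals over paired {0,1} mask lists."""
    if len(predictions) != len(references):
        raise ValueError(f"{len(predictions)} predictions vs {len(references)} references")
    t = ConfusionTotals()
    for i, (pred, ref) in enumerate(zip(predictions, references)):
        pred = np.asarray(pred)
        ref = np.asarray(ref)
        if pred.shape != ref.shape:
            raise ValueError(f"pair {i}: prediction {pred.shape} vs reference {ref.shape}")
        p = pred.astype(bool)
        r = ref.astype(bool)
        t.tp += int(np.count_nonzero(p & r))
        t.fp += int(np.count_nonzero(p & ~r))
        t.fn += int(np.count_nonzero(~p & r))
        t.tn += int(np.count_nonzero(~p & ~r))
    return t


def iou(t: ConfusionTotals) -> float:
    """Intersection over union of the marbling class; 1.0 if both empty."""
    union = t.tp + t.fn + t.fp
    if union == 0:
        warnings.warn("empty union (no marbling predicted or annotated); IoU := 1.0")
        return 1.0
    return t.tp / union


def precision(t: ConfusionTotals) -> float:
    if t.tp + t.fp == 0:
        warnings.warn("no positive predictions; precision := 0.0")
        return 0.0
    return t.tp / (t.tp + t.fp)


def recall(t: ConfusionTotals) -> float:
    if t.tp + t.fn == 0:
        warnings.warn("no positive references; recall := 0.0")
        return 0.0
    return t.tp / (t.tp + t.fn)


def f1(t: ConfusionTotals) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r = precision(t), recall(t)
    if p + r == 0:
        warnings.warn("precision + recall is zero; F1 := 0.0")
        return 0.0
    return 2 * p * r / (p + r)


def all_metrics(t: ConfusionTotals) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {"iou": iou(t), "precision": precision(t),
                "recall": recall(t), "f1": f1(t)}
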