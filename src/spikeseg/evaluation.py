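"""Segmentation and counting metrics.

Pixel level: precision, recall, accuracy, F1, Jaccard index (JI), the
overall misclassification rate E1 = (FP+FN)/total, and the class-balanced
error E2 = (FPR + FNR)/2.  Object level: the same precision/recall/F1 with
TN fixed at zero (background is not an object), which makes accuracy
TP/(TP+FP+FN), i.e. the object-level Jaccard index.

Dataset-level numbers are means of per-image metrics (mean of ratios), not
pooled confusions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


@dataclass
class PixelConfusion:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ObjectConfusion:
    tp: int
    fp: int
    fn: int
    tn: int = 0  # background is never an object in this problem

    def __post_init__(self):
        if self.tn != 0:
            raise ValueError("object-level TN is zero by definition")
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class SegMetrics:
    precision: float
    recall: float
    accuracy: float
    f1: float
    ji: float
    e1: float
    e2: float


def _binary(arr, name):
    arr = np.asarray(arr)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError(f"{name} must be binary with 1 = spike")
    return arr.astype(bool)


def pixel_confusion(predicted: np.ndarray, truth: np.ndarray) -> PixelConfusion:
    predicted = _binary(predicted, "predicted")
    truth = _binary(truth, "truth")
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}")
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    tn = int(np.sum(~predicted & ~truth))
    return PixelConfusion(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num, den, empty_value):
    return num / den if den > 0 else empty_value


def segmentation_metrics(c: PixelConfusion) -> SegMetrics:
    """All pixel metrics from one confusion.

    0/0 convention: precision (recall) is 1.0 when there are no predicted
    (actual) positives *and* the other side is empty too, else 0.0 - perfect
    agreement on an empty image is not penalized.
    """
    if c.total == 0:
        raise ValueError("empty confusion: no pixels compared")
    precision = _safe_ratio(c.tp, c.tp + c.fp, 1.0 if c.fn == 0 else 0.0)
    recall = _safe_ratio(c.tp, c.tp + c.fn, 1.0 if c.fp == 0 else 0.0)
    accuracy = (c.tp + c.tn) / c.total
    f1 = _safe_ratio(2 * precision * recall, precision + recall, 0.0)
    ji = _safe_ratio(c.tp, c.tp + c.fp + c.fn, 1.0)
    e1 = (c.fp + c.fn) / c.total
    fpr = _safe_ratio(c.fp, c.fp + c.tn, 0.0)
    fnr = _safe_ratio(c.fn, c.fn + c.tp, 0.0)
    return SegMetrics(precision=precision, recall=recall, accuracy=accuracy,
                      f1=f1, ji=ji, e1=e1, e2=0.5 * (fpr + fnr))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    return 2 * precision * recall / (precision + recall)


def jaccard_from_precision_recall(precision: float, recall: float) -> float:
    """JI = 1 / (1/p + 1/r - 1), the IoU implied by precision and recall."""
    return 1.0 / (1.0 / precision + 1.0 / recall - 1.0)


def counting_metrics(c: ObjectConfusion) -> Tuple[float, float, float, float]:
    """(precision, recall, accuracy, f1) at object level; TN = 0 makes
    accuracy = TP / (TP + FP + FN)."""
    if c.tp + c.fp + c.fn == 0:
        raise ValueError("empty object confusion")
    precision = _safe_ratio(c.tp, c.tp + c.fp, 1.0 if c.fn == 0 else 0.0)
    recall = _safe_ratio(c.tp, c.tp + c.fn, 1.0 if c.fp == 0 else 0.0)
    accuracy = c.tp / (c.tp + c.fp + c.fn)
    f1 = _safe_ratio(2 * precision * recall, precision + recall, 0.0)
    return precision, recall, accuracy, f1


def implied_error_pixels(e1: float, n_pixels: int) -> int:
    """Misclassified-pixel count implied by an error rate, rounded to nearest."""
    if not 0.0 <= e1 <= 1.0:
        raise ValueError(f"e1 must be in [0, 1], got {e1}")
    return int(round(e1 * n_pixels))


FN_PINK = (255, 105, 180)
FP_GREEN = (0, 200, 0)


def error_overlay(predicted: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Render disagreement over the ground truth: truth spikes black on a
    white background, missed spike pixels pink, spurious detections green."""
    predicted = _binary(predicted, "predicted")
    truth = _binary(truth, "truth")
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth dims differ")
    out = np.full(truth.shape + (3,), 255, dtype=np.uint8)
    out[truth] = (0, 0, 0)
    out[truth & ~predicted] = FN_PINK
    out[predicted & ~truth] = FP_GREEN
    return out


def evaluate_dataset(pairs: Sequence[Tuple[np.ndarray, np.ndarray]]
                     ) -> Tuple[List[SegMetrics], SegMetrics]:
    """Per-image metrics and their arithmetic mean over the dataset."""
    if len(pairs) == 0:
        raise ValueError("no (predicted, truth) pairs supplied")
    per_image = [segmentation_metrics(pixel_confusion(p, t)) for p, t in pairs]
    mean = SegMetrics(**{
        name: float(np.mean([getattr(m, name) for m in per_image]))
        for name in ("precision", "recall", "accuracy", "f1", "ji", "e1", "e2")
    })
    return per_image, mean
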