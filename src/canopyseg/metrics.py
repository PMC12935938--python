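"""Segmentation quality metrics from confusion matrices.

Pixel accuracy (PA), per-class intersection-over-union (IoU) and their
unweighted class mean (MIoU).  Counts are accumulated in a confusion matrix
(rows = ground truth, columns = prediction) so metrics over an image set
equal metrics over the pixel-wise concatenation of those images.
A class absent from both ground truth and prediction has an undefined
(0/0) IoU; it is reported as NaN and excluded from the MIoU mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "pixel_accuracy",
    "iou_per_class",
    "miou",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has an empty or all-undefined denominator."""


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    num_classes: int = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        self.num_classes = self.counts.shape[0]

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(gt: np.ndarray, pred: np.ndarray, num_classes: int) -> ConfusionMatrix:
    """Count pixels with ground-truth class i and predicted class j."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    g = gt.ravel().astype(np.int64)
    p = pred.ravel().astype(np.int64)
    if g.size and (g.min() < 0 or g.max() >= num_classes):
        raise ValueError(f"ground-truth labels outside [0, {num_classes})")
    if p.size and (p.min() < 0 or p.max() >= num_classes):
        raise ValueError(f"predicted labels outside [0, {num_classes})")
    counts = np.bincount(g * num_classes + p, minlength=num_classes * num_classes)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes))


def pixel_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of pixels whose predicted class matches the ground truth."""
    total = cm.total
    if total == 0:
        raise UndefinedMetricError("pixel accuracy of an empty confusion matrix")
    return float(np.trace(cm.counts) / total)


def iou_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """IoU_i = TP_i / (TP_i + FP_i + FN_i); NaN where the class never occurs."""
    if cm.total == 0:
        raise UndefinedMetricError("IoU of an empty confusion matrix")
    tp = np.diag(cm.counts).astype(float)
    union = cm.counts.sum(axis=0) + cm.counts.sum(axis=1) - np.diag(cm.counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, tp / union, np.nan)
    return iou


def miou(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the defined per-class IoUs."""
    iou = iou_per_class(cm)
    defined = iou[~np.isnan(iou)]
    if defined.size == 0:
        raise UndefinedMetricError("all class IoUs are undefined (0/0)")
    return float(defined.mean())
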