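"""Segmentation evaluation: confusion matrix, mPA and mIoU.

Mean Pixel Accuracy averages per-class recall ``n_ii / sum_j n_ij``;
mean Intersection-over-Union averages ``n_ii / (row_i + col_i - n_ii)``.
Classes absent from both truth and prediction are dropped from the
means (the convention of the FCN evaluation protocol); nodata pixels
in either raster are excluded from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MetricError
from .raster_io import Raster, assert_coregistered

__all__ = ["ConfusionMatrix", "confusion", "mean_pixel_accuracy",
           "mean_iou", "per_class_iou"]


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of pixels of true class i predicted as j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise MetricError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise MetricError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(pred, truth, n_classes: int = 3,
              ignore: float | None = None) -> ConfusionMatrix:
    """Tally the confusion matrix of two label rasters (or arrays).

    Pixels that are nodata in either input are excluded.
    """
    if isinstance(pred, Raster) and isinstance(truth, Raster):
        assert_coregistered(pred, truth)
        p = np.asarray(pred.data).ravel()
        t = np.asarray(truth.data).ravel()
        valid = (p != pred.nodata) & (t != truth.nodata)
    else:
        p = np.asarray(pred).ravel()
        t = np.asarray(truth).ravel()
        valid = np.ones(p.shape, dtype=bool)
        if ignore is not None:
            valid = (p != ignore) & (t != ignore)
    p, t = p[valid].astype(np.int64), t[valid].astype(np.int64)
    if p.size == 0:
        raise MetricError("no valid pixels to evaluate")
    counts = np.bincount(t * n_classes + p,
                         minlength=n_classes * n_classes)
    return ConfusionMatrix(counts=counts.reshape(n_classes, n_classes))


def _present(cm: ConfusionMatrix) -> np.ndarray:
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    return (row + col) > 0


def mean_pixel_accuracy(cm: ConfusionMatrix) -> float:
    """Mean over classes present in the truth of per-class recall."""
    if cm.total == 0:
        raise MetricError("empty confusion matrix")
    row = cm.counts.sum(axis=1)
    present = row > 0
    if not present.any():
        raise MetricError("no class present in truth")
    diag = np.diag(cm.counts)
    return float(np.mean(diag[present] / row[present]))


def per_class_iou(cm: ConfusionMatrix) -> np.ndarray:
    """IoU per class; NaN for classes absent from truth and prediction."""
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    union = row + col - diag
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, diag / np.maximum(union, 1), np.nan)


def mean_iou(cm: ConfusionMatrix) -> float:
    """Mean over present classes of intersection-over-union."""
    if cm.total == 0:
        raise MetricError("empty confusion matrix")
    iou = per_class_iou(cm)
    present = _present(cm)
    if not present.any():
        raise MetricError("no class present")
    return float(np.mean(iou[present]))
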