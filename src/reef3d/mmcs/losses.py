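"""Hybrid segmentation loss: cross entropy + weighted soft IoU.

The training objective is ``L = L_CE + mu * L_IoU`` with mu defaulting
to 0.4. Cross entropy supervises every pixel with a smooth gradient;
the soft IoU term is map-level — for each class c,

    I_c = sum p_c * y_c
    U_c = sum (p_c + y_c - p_c * y_c)
    L_IoU = 1 - mean_c I_c / U_c

averaged over the classes present in the labels or the argmax
prediction — which pushes whole predicted regions toward their target
shapes rather than individual pixels. Pixels labeled with the ignore
sentinel contribute to neither term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..classes import LABEL_NODATA
from ..errors import MetricError

__all__ = ["LossConfig", "softmax", "ce_loss", "soft_iou_loss",
           "hybrid_loss", "hybrid_loss_and_grad"]


@dataclass(frozen=True)
class LossConfig:
    """mu >= 0 weights the IoU term; ``foreground_only`` restricts the
    IoU average to classes 1+ (background excluded)."""

    mu: float = 0.4
    foreground_only: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _valid_mask(labels, ignore):
    return labels != ignore


def ce_loss(logits: np.ndarray, labels: np.ndarray,
            ignore: int = LABEL_NODATA) -> float:
    """Mean over non-ignored pixels of -log softmax p(true class).

    ``logits`` is (N, K, H, W); ``labels`` (N, H, W) integer.
    """
    valid = _valid_mask(labels, ignore)
    if not valid.any():
        raise MetricError("all pixels ignored: cross entropy undefined")
    p = softmax(logits)
    n, h, w = np.nonzero(valid)
    true_p = p[n, labels[valid].astype(np.int64), h, w]
    return float(-np.log(np.maximum(true_p, 1e-300)).mean())


def _iou_classes(probs, labels, valid, foreground_only):
    """Classes over which the IoU loss averages: present in labels or
    in the argmax prediction (within valid pixels)."""
    k = probs.shape[1]
    pred = np.argmax(probs, axis=1)
    present = set(np.unique(labels[valid]).astype(int).tolist())
    present |= set(np.unique(pred[valid]).astype(int).tolist())
    lo = 1 if foreground_only else 0
    return [c for c in range(lo, k) if c in present]


def soft_iou_loss(probs: np.ndarray, labels: np.ndarray,
                  ignore: int = LABEL_NODATA,
                  foreground_only: bool = False) -> float:
    """1 - mean per-class soft IoU (see module docstring).

    ``probs`` must already be softmax outputs (per-pixel simplex).
    """
    valid = _valid_mask(labels, ignore)
    if not valid.any():
        raise MetricError("all pixels ignored: IoU loss undefined")
    classes = _iou_classes(probs, labels, valid, foreground_only)
    if not classes:
        raise MetricError("no classes present for IoU loss")
    ious = []
    for c in classes:
        pc = probs[:, c][valid]
        yc = (labels[valid] == c).astype(np.float64)
        inter = float((pc * yc).sum())
        union = float((pc + yc - pc * yc).sum())
        ious.append(inter / union)
    return float(1.0 - np.mean(ious))


def hybrid_loss(logits: np.ndarray, labels: np.ndarray,
                lc: LossConfig = LossConfig(),
                ignore: int = LABEL_NODATA) -> float:
    """ce_loss + mu * soft_iou_loss."""
    ce = ce_loss(logits, labels, ignore=ignore)
    if lc.mu == 0:
        return ce
    iou = soft_iou_loss(softmax(logits), labels, ignore=ignore,
                        foreground_only=lc.foreground_only)
    return ce + lc.mu * iou


def hybrid_loss_and_grad(logits: np.ndarray, labels: np.ndarray,
                         lc: LossConfig = LossConfig(),
                         ignore: int = LABEL_NODATA):
    """Loss value plus its analytic gradient w.r.t. the logits.

    Returns ``(parts, dlogits)`` with ``parts = {"loss", "ce", "iou"}``.
    """
    valid = _valid_mask(labels, ignore)
    if not valid.any():
        raise MetricError("all pixels ignored: loss undefined")
    p = softmax(logits)
    n_valid = int(valid.sum())
    lab = labels.astype(np.int64)

    # cross entropy and its gradient w.r.t. probabilities' logits
    k = logits.shape[1]
    onehot = np.zeros_like(p)
    n, h, w = np.nonzero(valid)
    onehot[n, lab[valid], h, w] = 1.0
    true_p = p[n, lab[valid], h, w]
    ce = float(-np.log(np.maximum(true_p, 1e-300)).mean())
    dlogits = (p - onehot) * valid[:, None, :, :] / n_valid

    iou = 0.0
    if lc.mu > 0:
        classes = _iou_classes(p, labels, valid, lc.foreground_only)
        gp = np.zeros_like(p)        # d L_IoU / d p
        ious = []
        for c in classes:
            pc = p[:, c][valid]
            yc = (lab[valid] == c).astype(np.float64)
            inter = float((pc * yc).sum())
            union = float((pc + yc - pc * yc).sum())
            ious.append(inter / union)
            # d(I/U)/dp = (y * U - I * (1 - y)) / U^2 ; loss has a minus
            g = -(yc * union - inter * (1.0 - yc)) / (union * union)
            g /= len(classes)
            gp[:, c][valid] = g
        iou = float(1.0 - np.mean(ious))
        # chain through softmax: dz_k = p_k (g_k - sum_j g_j p_j)
        inner = (gp * p).sum(axis=1, keepdims=True)
        dlogits = dlogits + lc.mu * p * (gp - inner)

    loss = ce + lc.mu * iou
    return {"loss": loss, "ce": ce, "iou": iou}, dlogits
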