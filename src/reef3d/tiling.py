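"""Patch extraction, augmentation, cross-validation folds and stitching.

Scenes are tiled into ``window x window`` patches on a sliding grid
with a fixed stride (defaults 448 / 224, i.e. 50% overlap); patch
predictions are stitched back by averaging class probabilities on
overlaps and taking the argmax (ties broken toward the lower class
id). Augmentation applies the identical geometric transform to RGB,
height and label channels: rotations restricted to multiples of 90
degrees (lossless for the height channel) and translation by a
jittered crop offset when the source rasters are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classes import LABEL_NODATA
from .errors import ParameterError, TilingError
from .raster_io import Raster, assert_coregistered

__all__ = ["PatchRecord", "FoldSpec", "extract_patches", "augment_patch",
           "kfold_split", "stitch_predictions"]


@dataclass
class PatchRecord:
    """Aligned RGB + height (+ optional label) patch with its source
    grid offset ``origin = (row, col)``."""

    rgb: np.ndarray
    height: np.ndarray
    label: np.ndarray | None
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.height.shape
        if self.rgb.shape != (h, w, 3):
            raise ParameterError("rgb and height patches must align")
        if self.label is not None and self.label.shape != (h, w):
            raise ParameterError("label patch must align with rgb/height")

    @property
    def window(self) -> int:
        return self.height.shape[0]


@dataclass
class FoldSpec:
    """Assignment of each patch to exactly one validation fold."""

    n_folds: int
    assignment: np.ndarray
    seed: int

    def val_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment != fold)[0]


def grid_origins(extent: tuple[int, int], window: int, stride: int):
    """All (row, col) window origins on the sliding grid.

    ``floor((extent - window) / stride) + 1`` positions per axis."""
    rows, cols = extent
    if window > rows or window > cols:
        raise TilingError(f"window {window} exceeds extent {extent}")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    r_origins = [i * stride for i in range((rows - window) // stride + 1)]
    c_origins = [j * stride for j in range((cols - window) // stride + 1)]
    return [(r, c) for r in r_origins for c in c_origins]


def extract_patches(ortho: Raster, dsm: Raster, labels: Raster | None = None,
                    window: int = 448, stride: int = 224,
                    max_nodata_frac: float = 0.5) -> list[PatchRecord]:
    """Tile co-registered rasters into patches.

    Patches whose height (or label) channel is more than
    ``max_nodata_frac`` nodata are dropped.
    """
    assert_coregistered(ortho, dsm)
    if labels is not None:
        assert_coregistered(ortho, labels)
    out = []
    dsm_arr = np.asarray(dsm.data)
    for (r, c) in grid_origins(ortho.shape, window, stride):
        sl = (slice(r, r + window), slice(c, c + window))
        hp = dsm_arr[sl]
        bad = np.mean(hp == dsm.nodata)
        lp = None
        if labels is not None:
            lp = np.asarray(labels.data)[sl]
            bad = max(bad, np.mean(lp == labels.nodata))
        if bad > max_nodata_frac:
            continue
        out.append(PatchRecord(rgb=np.asarray(ortho.data)[sl].copy(),
                               height=hp.copy(),
                               label=None if lp is None else lp.copy(),
                               origin=(r, c)))
    return out


def augment_patch(p: PatchRecord, seed: int,
                  source: tuple[Raster, Raster, Raster] | None = None,
                  max_shift: int | None = None) -> PatchRecord:
    """Random 90-degree rotation plus (optionally) a translated re-crop.

    The same transform is applied to rgb, height and label; labels are
    categorical so only lossless operations are used. Translation
    jitters the crop origin by up to ``+-max_shift`` cells and needs
    the source ``(ortho, dsm, labels)`` rasters; without them the
    translation is 0 and only a rotation is applied.
    """
    if p.label is None:
        raise ParameterError("augmentation requires a labeled patch")
    rng = np.random.default_rng(seed)
    rgb, height, label = p.rgb, p.height, p.label
    origin = p.origin
    w = p.window

    if source is not None:
        ortho, dsm, labels = source
        shift = max_shift if max_shift is not None else w // 4
        rows, cols = ortho.shape
        r = int(np.clip(origin[0] + rng.integers(-shift, shift + 1), 0, rows - w))
        c = int(np.clip(origin[1] + rng.integers(-shift, shift + 1), 0, cols - w))
        sl = (slice(r, r + w), slice(c, c + w))
        rgb = np.asarray(ortho.data)[sl].copy()
        height = np.asarray(dsm.data)[sl].copy()
        label = np.asarray(labels.data)[sl].copy()
        origin = (r, c)

    k = int(rng.integers(0, 4))   # number of 90-degree CCW rotations
    if k:
        rgb = np.rot90(rgb, k, axes=(0, 1)).copy()
        height = np.rot90(height, k).copy()
        label = np.rot90(label, k).copy()
    return PatchRecord(rgb=rgb, height=height, label=label, origin=origin)


def kfold_split(n_patches: int, n_folds: int = 5, seed: int = 0) -> FoldSpec:
    """Partition patches into ``n_folds`` validation folds of sizes
    differing by at most one (shuffled round-robin)."""
    if n_patches < n_folds:
        raise ParameterError(
            f"cannot split {n_patches} patches into {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_patches)
    assignment = np.empty(n_patches, dtype=np.int64)
    assignment[perm] = np.arange(n_patches) % n_folds
    return FoldSpec(n_folds=n_folds, assignment=assignment, seed=seed)


def stitch_predictions(preds, extent: tuple[int, int],
                       transform, n_classes: int = 3):
    """Merge per-patch class probabilities into a full-scene label map.

    ``preds`` is a sequence of ``(origin, probs)`` with ``probs`` of
    shape (n_classes, h, w). Overlaps are resolved by averaging
    probabilities then argmax (ties toward the lower class id); cells
    covered by no patch are label nodata. Returns
    ``(label_raster, mean_probs array)``.
    """
    preds = list(preds)
    if not preds:
        raise TilingError("no predictions to stitch")
    rows, cols = extent
    acc = np.zeros((n_classes, rows, cols), dtype=np.float64)
    cnt = np.zeros((rows, cols), dtype=np.int64)
    for (r, c), probs in preds:
        probs = np.asarray(probs)
        _, h, w = probs.shape
        if r < 0 or c < 0 or r + h > rows or c + w > cols:
            raise TilingError(f"patch at {(r, c)} exceeds extent {extent}")
        acc[:, r:r + h, c:c + w] += probs
        cnt[r:r + h, c:c + w] += 1
    covered = cnt > 0
    mean = np.where(covered, acc / np.maximum(cnt, 1), 0.0)
    label = np.where(covered, np.argmax(mean, axis=0), LABEL_NODATA)
    raster = Raster(data=label.astype(np.uint8), transform=transform,
                    nodata=float(LABEL_NODATA), band_meaning="label")
    return raster, mean
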