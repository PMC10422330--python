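"""Training and full-scene inference for MMCS-Net.

Input normalisation: RGB is scaled to [0, 1] then standardised with
per-channel statistics of the training patches; the height patch has
its median subtracted and is divided by a fixed 0.05 m relief scale,
removing absolute depth while preserving relief amplitude (nodata
height cells are set to 0 after normalisation). Optimisation is Adam
with cosine learning-rate decay; augmentation draws a random
90-degree rotation per patch per epoch. Validation tracks patch-level
mPA/mIoU each epoch and the best-validation parameters are restored
at the end.
"""

from __future__ import annotations

import numpy as np

from ..classes import LABEL_NODATA
from ..errors import TrainingError
from ..metrics import confusion, mean_iou, mean_pixel_accuracy
from ..raster_io import Raster, assert_coregistered
from ..tiling import PatchRecord, extract_patches, stitch_predictions
from .layers import Adam
from .losses import LossConfig, hybrid_loss_and_grad, softmax
from .model import SegModel, restore_params, snapshot_params

__all__ = ["compute_norm_stats", "patches_to_arrays", "train",
           "train_single", "predict"]

DSM_SCALE = 0.05   # metres of relief mapped to one unit


def compute_norm_stats(patches) -> dict:
    """Per-channel RGB mean/std (on the [0, 1] scale) over patches."""
    pix = np.concatenate([p.rgb.reshape(-1, 3).astype(np.float64)
                          for p in patches]) / 255.0
    return {"rgb_mean": pix.mean(axis=0), "rgb_std": pix.std(axis=0) + 1e-8,
            "dsm_scale": DSM_SCALE}


def _patch_input(p: PatchRecord, stats: dict, use_dsm: bool,
                 height_nodata: float = -9999.0) -> np.ndarray:
    rgb = p.rgb.astype(np.float64) / 255.0
    rgb = (rgb - stats["rgb_mean"]) / stats["rgb_std"]
    chans = [rgb[:, :, c] for c in range(3)]
    if use_dsm:
        h = p.height.astype(np.float64)
        valid = h != height_nodata
        med = np.median(h[valid]) if valid.any() else 0.0
        hn = np.where(valid, (h - med) / stats["dsm_scale"], 0.0)
        chans.append(hn)
    return np.stack(chans, axis=0)


def patches_to_arrays(patches, stats, use_dsm):
    x = np.stack([_patch_input(p, stats, use_dsm) for p in patches])
    y = np.stack([p.label for p in patches]).astype(np.int64)
    return x, y


def _rot_batch(x, y, rng):
    """Independent random 90-degree rotation per sample."""
    ks = rng.integers(0, 4, size=len(x))
    xo, yo = x.copy(), y.copy()
    for i, k in enumerate(ks):
        if k:
            xo[i] = np.rot90(x[i], k, axes=(1, 2))
            yo[i] = np.rot90(y[i], k)
    return xo, yo


def evaluate(model: SegModel, x_val, y_val, batch_size: int = 8):
    """Patch-level mPA / mIoU of a model on pre-normalised arrays."""
    preds = []
    for i in range(0, len(x_val), batch_size):
        logits = model.net.forward(x_val[i:i + batch_size], training=False)
        preds.append(np.argmax(logits, axis=1))
    pred = np.concatenate(preds)
    cm = confusion(pred, y_val, n_classes=model.config.n_classes,
                   ignore=LABEL_NODATA)
    return {"mPA": mean_pixel_accuracy(cm), "mIoU": mean_iou(cm)}


def train_single(model: SegModel, train_patches, val_patches,
                 epochs: int = 30, batch_size: int = 16, lr: float = 1e-3,
                 seed: int = 0, augment: bool = True,
                 cosine_decay: bool = True) -> list[dict]:
    """Train on one split; returns the per-epoch history and leaves the
    model at its best-validation-mIoU parameters."""
    if not train_patches:
        raise TrainingError("no training patches")
    rng = np.random.default_rng(seed)
    model.norm_stats = compute_norm_stats(train_patches)
    model.window = train_patches[0].window
    use_dsm = model.config.use_dsm
    x_tr, y_tr = patches_to_arrays(train_patches, model.norm_stats, use_dsm)
    if val_patches:
        x_va, y_va = patches_to_arrays(val_patches, model.norm_stats, use_dsm)
    else:
        x_va = y_va = np.empty(0)

    opt = Adam(model.net.parameters(), lr=lr)
    n = len(x_tr)
    steps_per_epoch = max(1, (n + batch_size - 1) // batch_size)
    total_steps = epochs * steps_per_epoch
    history = []
    best = (-1.0, None)
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            if augment:
                xb, yb = _rot_batch(xb, yb, rng)
            logits = model.net.forward(xb, training=True)
            parts, dlogits = hybrid_loss_and_grad(logits, yb,
                                                  model.loss_config)
            if not np.isfinite(parts["loss"]):
                raise TrainingError(f"loss diverged at epoch {epoch}")
            opt.zero_grad()
            model.net.backward(dlogits)
            lr_t = lr
            if cosine_decay and lr > 0:
                lr_t = lr * 0.5 * (1 + np.cos(np.pi * step / max(total_steps, 1)))
            opt.step(lr=lr_t)
            epoch_loss += parts["loss"] * len(idx)
            step += 1
        val = evaluate(model, x_va, y_va) if len(x_va) else {"mPA": np.nan,
                                                             "mIoU": np.nan}
        rec = {"epoch": epoch, "train_loss": epoch_loss / n, **val}
        history.append(rec)
        if len(x_va) and val["mIoU"] > best[0]:
            best = (val["mIoU"], snapshot_params(model.net))
    if best[1] is not None:
        restore_params(model.net, best[1])
    return history


def train(model_factory, patches, folds, epochs: int = 30,
          batch_size: int = 16, lr: float = 1e-3, seed: int = 0,
          augment: bool = True):
    """Cross-validated training: one fresh model per fold.

    ``model_factory(fold)`` builds a :class:`SegModel`; fold ``f``
    validates on its fold and trains on the rest. Returns
    ``(models, histories, averaged final metrics)``.
    """
    models, histories = [], []
    for f in range(folds.n_folds):
        tr = [patches[i] for i in folds.train_indices(f)]
        va = [patches[i] for i in folds.val_indices(f)]
        if not tr:
            raise TrainingError(f"fold {f} has no training patches")
        model = model_factory(f)
        hist = train_single(model, tr, va, epochs=epochs,
                            batch_size=batch_size, lr=lr,
                            seed=seed + f, augment=augment)
        models.append(model)
        histories.append(hist)
    final = {k: float(np.mean([h[-1][k] for h in histories]))
             for k in ("mPA", "mIoU")}
    return models, histories, final


def predict(model: SegModel, ortho: Raster, dsm: Raster,
            window: int | None = None, stride: int | None = None,
            batch_size: int = 8):
    """Tile, normalise, forward and stitch a full scene.

    Returns ``(label_raster, mean_probs)`` with the label raster
    co-registered to the inputs; probabilities are averaged over
    overlapping tiles before the argmax.
    """
    assert_coregistered(ortho, dsm)
    window = window or min(model.window, *ortho.shape)
    stride = stride or max(1, window // 2)
    patches = extract_patches(ortho, dsm, labels=None, window=window,
                              stride=stride, max_nodata_frac=1.0)
    use_dsm = model.config.use_dsm
    preds = []
    for i in range(0, len(patches), batch_size):
        chunk = patches[i:i + batch_size]
        x = np.stack([_patch_input(p, model.norm_stats, use_dsm,
                                   height_nodata=dsm.nodata) for p in chunk])
        logits = model.net.forward(x, training=False)
        probs = softmax(logits)
        preds.extend((p.origin, probs[j]) for j, p in enumerate(chunk))
    return stitch_predictions(preds, ortho.shape, ortho.transform,
                              n_classes=model.config.n_classes)
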