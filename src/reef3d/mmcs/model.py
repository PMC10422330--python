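"""The multi-modal coral segmentation network (MMCS-Net).

A DeepLabv3+-style encoder-decoder over a 4-channel RGB+height input:
a residual convolutional encoder whose convolutions are shape-aware
(ShapeConv) in the full model, atrous spatial pyramid pooling (ASPP)
over the encoder output, and a light decoder that fuses a low-level
feature tap through depthwise-separable convolutions before the
classifier. Ablation switches reproduce the reference variants:
``use_dsm=False`` is the RGB-only baseline (Model A),
``use_shapeconv=False`` the plain-convolution RGB+DSM variant
(Model B); both flags on is the full network.

Two presets are provided: ``tiny`` (a few thousand parameters,
trainable on one CPU core; used throughout the test suite) and
``full`` (a deeper encoder for real scenes).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (Adam, BatchNorm2d, Conv2d, DepthwiseConv2d, Layer,
                     ReLU, Sequential, ShapeConv2d, UpsampleNearest)
from .losses import LossConfig

__all__ = ["ModelConfig", "MMCSNet", "build_model", "SegModel",
           "save_checkpoint", "load_checkpoint"]

_PRESETS = {
    # channels: stem, enc1 (low-level tap), enc2; aspp branch width
    "tiny": {"stem": 12, "enc1": 16, "enc2": 24, "aspp": 16,
             "lowlevel": 8, "decoder": 24, "aspp_rates": (1, 2, 4)},
    "full": {"stem": 32, "enc1": 64, "enc2": 128, "aspp": 64,
             "lowlevel": 32, "decoder": 96, "aspp_rates": (1, 6, 12, 18)},
}


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 4
    n_classes: int = 3
    preset: str = "tiny"
    use_shapeconv: bool = True
    use_dsm: bool = True
    aspp_rates: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    @property
    def effective_in_channels(self) -> int:
        return self.in_channels if self.use_dsm else 3

    @property
    def output_stride(self) -> int:
        return 4

    @property
    def rates(self) -> tuple:
        return self.aspp_rates or _PRESETS[self.preset]["aspp_rates"]


def _conv_bn_relu(conv_cls, c_in, c_out, k, rng, stride=1, dilation=1):
    return Sequential(conv_cls(c_in, c_out, k, rng, stride=stride,
                               dilation=dilation),
                      BatchNorm2d(c_out), ReLU())


class ResidualBlock(Layer):
    """Two 3x3 convolutions with identity skip and post-add ReLU."""

    def __init__(self, conv_cls, c, rng):
        self.body = Sequential(
            conv_cls(c, c, 3, rng), BatchNorm2d(c), ReLU(),
            conv_cls(c, c, 3, rng), BatchNorm2d(c))
        self.relu = ReLU()

    def forward(self, x, training=False):
        y = self.body.forward(x, training=training) + x
        return self.relu.forward(y, training=training)

    def backward(self, gout):
        g = self.relu.backward(gout)
        return self.body.backward(g) + g


class ASPP(Layer):
    """Atrous spatial pyramid pooling: parallel dilated 3x3 branches, a
    1x1 branch, and a global-average image branch, concatenated and
    projected."""

    def __init__(self, c_in, branch_c, c_out, rates, rng):
        self.branches = []
        for r in rates:
            if r == 1:
                self.branches.append(_conv_bn_relu(Conv2d, c_in, branch_c, 1, rng))
            else:
                self.branches.append(_conv_bn_relu(Conv2d, c_in, branch_c, 3,
                                                   rng, dilation=r))
        self.image_conv = Conv2d(c_in, branch_c, 1, rng)
        self.image_relu = ReLU()
        n_cat = branch_c * (len(rates) + 1)
        self.project = _conv_bn_relu(Conv2d, n_cat, c_out, 1, rng)
        self.branch_c = branch_c

    def forward(self, x, training=False):
        self._hw = x.shape[2:]
        outs = [b.forward(x, training=training) for b in self.branches]
        gap = x.mean(axis=(2, 3), keepdims=True)
        img = self.image_relu.forward(
            self.image_conv.forward(gap, training=training), training=training)
        outs.append(np.broadcast_to(img, img.shape[:2] + self._hw).copy())
        cat = np.concatenate(outs, axis=1)
        return self.project.forward(cat, training=training)

    def backward(self, gout):
        gcat = self.project.backward(gout)
        c = self.branch_c
        gx = None
        for i, b in enumerate(self.branches):
            g = b.backward(gcat[:, i * c:(i + 1) * c])
            gx = g if gx is None else gx + g
        g_img = gcat[:, len(self.branches) * c:]
        g_img = g_img.sum(axis=(2, 3), keepdims=True)
        g_gap = self.image_conv.backward(self.image_relu.backward(g_img))
        h, w = self._hw
        gx = gx + g_gap / (h * w)    # mean-pool backward, broadcast
        return gx


class MMCSNet(Layer):
    """Encoder-decoder segmentation network; see module docstring.

    Maps (N, C_in, H, W) -> (N, n_classes, H, W) logits; H and W are
    padded internally to a multiple of the output stride.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        p = _PRESETS[cfg.preset]
        enc_conv = ShapeConv2d if cfg.use_shapeconv else Conv2d
        c_in = cfg.effective_in_channels

        self.stem = _conv_bn_relu(enc_conv, c_in, p["stem"], 3, rng)
        self.enc1 = _conv_bn_relu(enc_conv, p["stem"], p["enc1"], 3, rng,
                                  stride=2)
        self.enc2 = _conv_bn_relu(enc_conv, p["enc1"], p["enc2"], 3, rng,
                                  stride=2)
        self.res = ResidualBlock(enc_conv, p["enc2"], rng)
        self.aspp = ASPP(p["enc2"], p["aspp"], p["enc2"], cfg.rates, rng)
        self.up1 = UpsampleNearest(2)
        self.lowlevel = _conv_bn_relu(Conv2d, p["enc1"], p["lowlevel"], 1, rng)
        # decoder: depthwise-separable 3x3 then pointwise projection
        dec_in = p["enc2"] + p["lowlevel"]
        self.decoder = Sequential(
            DepthwiseConv2d(dec_in, 3, rng),
            Conv2d(dec_in, p["decoder"], 1, rng),
            BatchNorm2d(p["decoder"]), ReLU())
        self.classifier = Conv2d(p["decoder"], cfg.n_classes, 1, rng)
        self.up2 = UpsampleNearest(2)
        self._ll_c = p["lowlevel"]

    def forward(self, x, training=False):
        stride = self.cfg.output_stride
        N, C, H, W = x.shape
        ph = (-H) % stride
        pw = (-W) % stride
        self._pad_hw = (H, W)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        x0 = self.stem.forward(x, training=training)
        x1 = self.enc1.forward(x0, training=training)
        x2 = self.enc2.forward(x1, training=training)
        x3 = self.res.forward(x2, training=training)
        a = self.aspp.forward(x3, training=training)
        u = self.up1.forward(a, training=training)
        ll = self.lowlevel.forward(x1, training=training)
        cat = np.concatenate([u, ll], axis=1)
        d = self.decoder.forward(cat, training=training)
        logits = self.classifier.forward(d, training=training)
        out = self.up2.forward(logits, training=training)
        self._padded = (ph, pw)
        return out[:, :, :H, :W]

    def backward(self, gout):
        H, W = self._pad_hw
        ph, pw = self._padded
        if ph or pw:
            gout = np.pad(gout, ((0, 0), (0, 0), (0, ph), (0, pw)))
        g = self.up2.backward(gout)
        g = self.classifier.backward(g)
        g = self.decoder.backward(g)
        c_main = g.shape[1] - self._ll_c
        g_u, g_ll = g[:, :c_main], g[:, c_main:]
        g1_ll = self.lowlevel.backward(g_ll)
        g_a = self.up1.backward(g_u)
        g3 = self.aspp.backward(g_a)
        g2 = self.res.backward(g3)
        g1 = self.enc2.backward(g2) + g1_ll
        g0 = self.enc1.backward(g1)
        gx = self.stem.backward(g0)
        if ph or pw:
            gx = gx[:, :, :H, :W]
        return gx


def build_model(cfg: ModelConfig) -> MMCSNet:
    """Construct an MMCS-Net (deterministic for a fixed cfg.seed)."""
    return MMCSNet(cfg)


@dataclass
class SegModel:
    """A network together with its config, loss config and the input
    normalisation statistics learned from the training patches."""

    net: MMCSNet
    config: ModelConfig
    loss_config: LossConfig = field(default_factory=LossConfig)
    norm_stats: dict = field(default_factory=dict)
    window: int = 448


def save_checkpoint(model: SegModel, path) -> None:
    """Single-file archive: JSON config + parameter/buffer blobs."""
    params = model.net.parameters()
    meta = {
        "config": asdict(model.config),
        "loss_config": asdict(model.loss_config),
        "norm_stats": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in model.norm_stats.items()},
        "window": model.window,
    }
    buf = io.BytesIO()
    arrays = {f"p{i}": p.value for i, p in enumerate(params)}
    arrays.update(_bn_buffers(model.net))
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path) -> SegModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        data = np.load(io.BytesIO(zf.read("params.npz")))
        cfg_d = meta["config"]
        if cfg_d.get("aspp_rates") is not None:
            cfg_d["aspp_rates"] = tuple(cfg_d["aspp_rates"])
        cfg = ModelConfig(**cfg_d)
        net = build_model(cfg)
        for i, p in enumerate(net.parameters()):
            p.value[...] = data[f"p{i}"]
        _restore_bn_buffers(net, data)
        stats = {k: (np.asarray(v) if isinstance(v, list) else v)
                 for k, v in meta["norm_stats"].items()}
        return SegModel(net=net, config=cfg,
                        loss_config=LossConfig(**meta["loss_config"]),
                        norm_stats=stats, window=meta["window"])


def _iter_bn(layer, prefix="net"):
    for name, v in vars(layer).items():
        if isinstance(v, BatchNorm2d):
            yield f"{prefix}.{name}", v
        if isinstance(v, Layer):
            yield from _iter_bn(v, f"{prefix}.{name}")
        elif isinstance(v, (list, tuple)):
            for i, item in enumerate(v):
                if isinstance(item, BatchNorm2d):
                    yield f"{prefix}.{name}[{i}]", item
                if isinstance(item, Layer):
                    yield from _iter_bn(item, f"{prefix}.{name}[{i}]")


def _bn_buffers(net):
    out = {}
    for key, bn in _iter_bn(net):
        out[f"{key}.running_mean"] = bn.running_mean
        out[f"{key}.running_var"] = bn.running_var
    return out


def _restore_bn_buffers(net, data):
    for key, bn in _iter_bn(net):
        bn.running_mean = data[f"{key}.running_mean"].copy()
        bn.running_var = data[f"{key}.running_var"].copy()


def snapshot_params(net) -> list[np.ndarray]:
    arrs = [p.value.copy() for p in net.parameters()]
    arrs.append({k: v.copy() for k, v in _bn_buffers(net).items()})
    return arrs


def restore_params(net, snapshot) -> None:
    *values, buffers = snapshot
    for p, v in zip(net.parameters(), values):
        p.value[...] = v
    _restore_bn_buffers(net, buffers)
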