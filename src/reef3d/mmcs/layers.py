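"""Neural-network building blocks with explicit forward/backward passes.

Small, CPU-oriented layer library (im2col convolutions, batch norm,
nearest upsampling, Adam) used to assemble the multi-modal coral
segmentation network. The one non-standard layer is the shape-aware
convolution (ShapeConv): every K x K receptive-field window ``P`` is
split into a base component (its spatial mean per channel) and a shape
component (the residual), each reweighted by a learnable weight before
the usual kernel dot product:

    base  = mean_window(P)                 (per channel)
    shape = P - base
    P'    = w_base * base + w_shape o shape
    out   = kernel * P'

With ``w_base = w_shape = 1`` the recombination is the identity and
the layer degenerates exactly to a vanilla convolution; after training
the learned weights fold into the kernel (:meth:`ShapeConv2d.folded`),
so inference costs nothing extra.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Layer", "Conv2d", "ShapeConv2d", "DepthwiseConv2d",
           "BatchNorm2d", "ReLU", "UpsampleNearest", "Sequential", "Adam"]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer: forward caches what backward needs."""

    def parameters(self) -> list[Param]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.parameters())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, training=False):
        return self.forward(x, training=training)


def _im2col(x, k, stride, dilation, pad):
    """(N, C, H, W) -> windows (N, C, Ho, Wo, k, k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ke = (k - 1) * dilation + 1
    win = sliding_window_view(x, (ke, ke), axis=(2, 3))
    return win[:, :, ::stride, ::stride, ::dilation, ::dilation]


def _col2im(gcols, x_shape, k, stride, dilation, pad):
    """Adjoint of :func:`_im2col`; gcols is (N, C, Ho, Wo, k, k)."""
    N, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho, Wo = gcols.shape[2], gcols.shape[3]
    gx = np.zeros((N, C, Hp, Wp), dtype=gcols.dtype)
    for ki in range(k):
        for kj in range(k):
            gx[:, :,
               ki * dilation: ki * dilation + stride * Ho: stride,
               kj * dilation: kj * dilation + stride * Wo: stride] \
                += gcols[:, :, :, :, ki, kj]
    if pad:
        gx = gx[:, :, pad:pad + H, pad:pad + W]
    return gx


def _he_init(rng, c_out, c_in, k):
    fan_in = c_in * k * k
    return rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)


class Conv2d(Layer):
    """Standard 2D convolution ('same' output size at stride 1)."""

    def __init__(self, c_in, c_out, k, rng, stride=1, dilation=1, bias=True):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.dilation = stride, dilation
        self.pad = dilation * (k - 1) // 2
        self.weight = Param(_he_init(rng, c_out, c_in, k))
        self.bias = Param(np.zeros(c_out)) if bias else None

    def forward(self, x, training=False):
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {x.shape[1]}")
        self._x_shape = x.shape
        cols = _im2col(x, self.k, self.stride, self.dilation, self.pad)
        N, C, Ho, Wo, k, _ = cols.shape
        x2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
        self._x2, self._out_hw = x2, (Ho, Wo)
        W2 = self.weight.value.reshape(self.c_out, -1)
        y = x2 @ W2.T
        if self.bias is not None:
            y += self.bias.value
        return y.reshape(N, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gout):
        N = self._x_shape[0]
        Ho, Wo = self._out_hw
        g2 = gout.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.c_out)
        self.weight.grad += (g2.T @ self._x2).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        W2 = self.weight.value.reshape(self.c_out, -1)
        gcols = (g2 @ W2).reshape(N, Ho, Wo, self.c_in, self.k, self.k)
        gcols = gcols.transpose(0, 3, 1, 2, 4, 5)
        return _col2im(gcols, self._x_shape, self.k, self.stride,
                       self.dilation, self.pad)


class ShapeConv2d(Layer):
    """Shape-aware convolution (see module docstring).

    ``w_base`` is one weight per input channel; ``w_shape`` one weight
    per input channel and kernel position. Both initialise to 1, so an
    untrained layer equals the vanilla convolution with the same
    kernel.
    """

    def __init__(self, c_in, c_out, k, rng, stride=1, dilation=1, bias=True):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.dilation = stride, dilation
        self.pad = dilation * (k - 1) // 2
        self.weight = Param(_he_init(rng, c_out, c_in, k))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self.w_base = Param(np.ones(c_in))
        self.w_shape = Param(np.ones((c_in, k, k)))

    def forward(self, x, training=False):
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {x.shape[1]}")
        self._x_shape = x.shape
        cols = _im2col(x, self.k, self.stride, self.dilation, self.pad)
        colsT = cols.transpose(0, 2, 3, 1, 4, 5)           # N,Ho,Wo,C,k,k
        base = colsT.mean(axis=(4, 5), keepdims=True)
        shape = colsT - base
        pp = self.w_base.value[:, None, None] * base + self.w_shape.value * shape
        N, Ho, Wo = colsT.shape[:3]
        x2 = pp.reshape(N * Ho * Wo, self.c_in * self.k * self.k)
        self._base, self._shape = base, shape
        self._x2, self._out_hw = x2, (Ho, Wo)
        W2 = self.weight.value.reshape(self.c_out, -1)
        y = x2 @ W2.T
        if self.bias is not None:
            y += self.bias.value
        return y.reshape(N, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gout):
        N = self._x_shape[0]
        Ho, Wo = self._out_hw
        k = self.k
        g2 = gout.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.c_out)
        self.weight.grad += (g2.T @ self._x2).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        W2 = self.weight.value.reshape(self.c_out, -1)
        gpp = (g2 @ W2).reshape(N, Ho, Wo, self.c_in, k, k)

        self.w_shape.grad += (gpp * self._shape).sum(axis=(0, 1, 2))
        self.w_base.grad += (gpp.sum(axis=(4, 5))
                             * self._base[..., 0, 0]).sum(axis=(0, 1, 2))

        through_base = ((self.w_base.value[:, None, None] - self.w_shape.value)
                        * gpp).sum(axis=(4, 5), keepdims=True) / (k * k)
        gcolsT = self.w_shape.value * gpp + through_base
        gcols = gcolsT.transpose(0, 3, 1, 2, 4, 5)
        return _col2im(gcols, self._x_shape, k, self.stride,
                       self.dilation, self.pad)

    def folded(self, rng=None) -> Conv2d:
        """Fold the learned base/shape weights into an equivalent plain
        convolution (the inference-time form)."""
        k = self.k
        conv = Conv2d.__new__(Conv2d)
        conv.c_in, conv.c_out, conv.k = self.c_in, self.c_out, k
        conv.stride, conv.dilation, conv.pad = self.stride, self.dilation, self.pad
        W = self.weight.value                       # (cout, cin, k, k)
        ws = self.w_shape.value                     # (cin, k, k)
        wb = self.w_base.value                      # (cin,)
        corr = (W * (wb[None, :, None, None] - ws[None])).sum(
            axis=(2, 3), keepdims=True) / (k * k)
        conv.weight = Param(W * ws[None] + corr)
        conv.bias = None if self.bias is None else Param(self.bias.value.copy())
        return conv


class DepthwiseConv2d(Layer):
    """Per-channel (depthwise) convolution, multiplier 1."""

    def __init__(self, c, k, rng, stride=1, dilation=1, bias=True):
        self.c, self.k = c, k
        self.stride, self.dilation = stride, dilation
        self.pad = dilation * (k - 1) // 2
        self.weight = Param(rng.standard_normal((c, k, k)) * np.sqrt(2.0 / (k * k)))
        self.bias = Param(np.zeros(c)) if bias else None

    def forward(self, x, training=False):
        self._x_shape = x.shape
        cols = _im2col(x, self.k, self.stride, self.dilation, self.pad)
        self._cols = cols                           # N,C,Ho,Wo,k,k
        y = np.einsum("nchwkl,ckl->nchw", cols, self.weight.value)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, gout):
        self.weight.grad += np.einsum("nchwkl,nchw->ckl", self._cols, gout)
        if self.bias is not None:
            self.bias.grad += gout.sum(axis=(0, 2, 3))
        gcols = np.einsum("nchw,ckl->nchwkl", gout, self.weight.value)
        return _col2im(gcols, self._x_shape, self.k, self.stride,
                       self.dilation, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._xhat, self._std, self._training = xhat, std, training
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, gout):
        xhat, std = self._xhat, self._std
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not self._training:
            return gout * g / std[None, :, None, None]
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        gy = gout * g
        mean_gy = gy.mean(axis=(0, 2, 3), keepdims=True)
        mean_gy_xhat = (gy * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (gy - mean_gy - xhat * mean_gy_xhat) / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout):
        return np.where(self._mask, gout, 0.0)


class UpsampleNearest(Layer):
    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, training=False):
        f = self.factor
        return np.repeat(np.repeat(x, f, axis=2), f, axis=3)

    def backward(self, gout):
        f = self.factor
        N, C, H, W = gout.shape
        return gout.reshape(N, C, H // f, f, W // f, f).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
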