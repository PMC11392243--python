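"""Minimal CPU convolutional-network library.

Small, explicit layer classes with hand-written backpropagation and an Adam
optimizer, written against numpy only.  It exists to support the two networks
in this package — the U-shaped segmentation network and the compact temporal
ConvNet backbone — at phantom scale on a single CPU core.  It is deliberately
not a general autodiff framework: each network composes layers and calls
``forward``/``backward`` explicitly, and every layer caches what its backward
pass needs from the most recent forward call.

All tensors are ``float32`` in NCHW layout.  All parameter initialisation
draws from a ``numpy.random.Generator`` passed in by the caller, so a single
integer seed makes construction and training bit-reproducible (given fixed
BLAS thread settings).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "MaxPool2d",
    "AdaptiveMaxPool2d",
    "Linear",
    "Adam",
    "softmax",
    "log_softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """2-D convolution ("same" zero padding) with optional stride.

    Uses a sliding-window view + tensordot for the forward pass and an
    explicit kxk scatter loop for the input gradient, which keeps memory
    bounded and is fast at the sizes used here.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Param(rng.normal(0.0, scale, (out_ch, in_ch, ksize, ksize)))
        self.bias = Param(np.zeros(out_ch)) if bias else None
        self.in_ch, self.out_ch, self.ksize, self.stride = in_ch, out_ch, ksize, stride
        self.pad = ksize // 2
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        p, s, k = self.pad, self.stride, self.ksize
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # (N, C, Ho, Wo, k, k) view
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._cols = cols
        self._xshape = x.shape
        y = np.tensordot(cols, self.weight.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(np.moveaxis(y, 3, 1), dtype=np.float32)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        p, s, k = self.pad, self.stride, self.ksize
        cols = self._cols
        # dW: correlate cached input windows with the output gradient
        gw = np.tensordot(gy, cols, axes=([0, 2, 3], [0, 2, 3]))  # (out, C, k, k)
        self.weight.grad += gw
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        n, _, h, w = self._xshape
        ho, wo = gy.shape[2], gy.shape[3]
        gxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=np.float32)
        wv = self.weight.value
        for i in range(k):
            for j in range(k):
                # (N,out,Ho,Wo) x (out,in) -> (N,in,Ho,Wo)
                contrib = np.tensordot(gy, wv[:, :, i, j], axes=([1], [0]))
                contrib = np.moveaxis(contrib, 3, 1)
                gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += contrib
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (the 'up-convolution')."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_ch)
        self.weight = Param(rng.normal(0.0, scale, (in_ch, out_ch, 2, 2)))
        self.bias = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        # y[n,o,2h+i,2w+j] = sum_c x[n,c,h,w] * W[c,o,i,j]
        y = np.einsum("nchw,coij->nohiwj", x, self.weight.value, optimize=True)
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w)
        y += self.bias.value[None, :, None, None]
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        g = gy.reshape(n, self.out_ch, h, 2, w, 2)
        self.weight.grad += np.einsum("nchw,nohiwj->coij", x, g, optimize=True)
        self.bias.grad += gy.sum(axis=(0, 2, 3))
        gx = np.einsum("nohiwj,coij->nchw", g, self.weight.value, optimize=True)
        return np.ascontiguousarray(gx, dtype=np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0).astype(np.float32)


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._inshape = x.shape
        return np.ascontiguousarray(flat.max(axis=-1), dtype=np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gflat, self._argmax[..., None], gy[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gx.reshape(n, c, h, w), dtype=np.float32)


class AdaptiveMaxPool2d(Layer):
    """Max-pool to a fixed output grid; input dims must divide evenly."""

    def __init__(self, out_hw: tuple[int, int]):
        self.out_hw = out_hw

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self.out_hw
        if h % oh or w % ow:
            raise ValueError(f"cannot pool {h}x{w} adaptively to {oh}x{ow}")
        bh, bw = h // oh, w // ow
        blocks = x.reshape(n, c, oh, bh, ow, bw)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, bh * bw)
        self._argmax = flat.argmax(axis=-1)
        self._inshape = x.shape
        return np.ascontiguousarray(flat.max(axis=-1), dtype=np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        oh, ow = self.out_hw
        bh, bw = h // oh, w // ow
        gflat = np.zeros((n, c, oh, ow, bh * bw), dtype=np.float32)
        np.put_along_axis(gflat, self._argmax[..., None], gy[..., None], axis=-1)
        gx = gflat.reshape(n, c, oh, ow, bh, bw).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gx.reshape(n, c, h, w), dtype=np.float32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, scale, (out_features, in_features)))
        self.bias = Param(np.zeros(out_features))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (x @ self.weight.value.T + self.bias.value).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        return (gy @ self.weight.value).astype(np.float32)


class Adam:
    """Adam with the standard bias correction; lr=0 leaves parameters untouched."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    zm = z - z.max(axis=axis, keepdims=True)
    e = np.exp(zm)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    zm = z - z.max(axis=axis, keepdims=True)
    return zm - np.log(np.exp(zm).sum(axis=axis, keepdims=True))


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray,
                          class_axis: int = 1) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over all non-class axes.

    Returns ``(loss, dloss/dlogits)``.  Works for (N, C) score matrices and
    for dense per-pixel (N, C, H, W) logit maps alike.
    """
    ls = log_softmax(logits, axis=class_axis)
    n_items = logits.size // logits.shape[class_axis]
    loss = -float((onehot * ls).sum()) / n_items
    grad = (softmax(logits, axis=class_axis) - onehot) / n_items
    return loss, grad.astype(np.float32)
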