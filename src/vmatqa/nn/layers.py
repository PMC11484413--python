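"""Layers with explicit caches and hand-derived backward passes.

Conventions: activations are float32 arrays; images are channels-last,
(B, H, W, C), which lets the 3x3 convolutions run as a single GEMM over a
contiguous patch matrix (the dominant cost on one CPU core).
``forward(x, train=..., update_stats=...)`` returns ``(y, cache)``;
``backward(dy, cache)`` accumulates parameter gradients in ``Param.grad``
and returns ``dx``.  Gradients are of a scalar loss w.r.t. the arrays.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data.astype(F32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x, train: bool = True, update_stats: bool = True):
        raise NotImplementedError

    def backward(self, dy, cache):
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def params(self) -> List[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train: bool = True, update_stats: bool = True):
        caches = []
        for l in self.layers:
            x, c = l.forward(x, train=train, update_stats=update_stats)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches, need_input_grad: bool = True):
        n = len(self.layers)
        for i, (l, c) in enumerate(zip(reversed(self.layers), reversed(caches))):
            if i == n - 1 and not need_input_grad and isinstance(l, Conv2d):
                l.backward(dy, c, need_dx=False)
                return None
            dy = l.backward(dy, c)
        return dy


def _patches3(x: np.ndarray, stride: int) -> Tuple[np.ndarray, int, int]:
    """3x3/pad-1 patch matrix (B*oh*ow, 9*C), patch order (di, dj, c)."""
    b, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    v = sliding_window_view(xp, (3, 3), axis=(1, 2))[:, ::stride, ::stride]
    oh, ow = v.shape[1], v.shape[2]
    patches = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(
        b * oh * ow, 9 * c
    )
    return patches, oh, ow


class Conv2d(Layer):
    """3x3 convolution, padding 1, stride 1 or 2, channels-last.

    Runs as a single GEMM over the patch matrix; the input gradient is the
    matching transposed convolution (stride 2 dilates dy with zeros first),
    also a patch GEMM, which avoids slow scatter-adds.
    """

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = Param(rng.normal(0.0, scale, size=(9 * c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def _w_flipped(self) -> np.ndarray:
        """(9*F, C) kernel of the transposed convolution."""
        w4 = self.w.data.reshape(3, 3, self.c_in, self.c_out)
        return np.ascontiguousarray(
            w4[::-1, ::-1].transpose(0, 1, 3, 2)
        ).reshape(9 * self.c_out, self.c_in)

    def forward(self, x, train=True, update_stats=True):
        b = x.shape[0]
        patches, oh, ow = _patches3(x, self.stride)
        y = patches @ self.w.data + self.b.data
        return y.reshape(b, oh, ow, self.c_out), (patches, x.shape, oh, ow)

    def backward(self, dy, cache, need_dx: bool = True):
        patches, x_shape, oh, ow = cache
        b, h, w, c = x_shape
        dyf = dy.reshape(b * oh * ow, self.c_out)
        self.w.grad += patches.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        if not need_dx:
            return None
        if self.stride == 1:
            dyz = dy
        else:  # fractional stride: dilate with zeros back to the input grid
            dyz = np.zeros((b, h, w, self.c_out), dtype=F32)
            dyz[:, :: self.stride, :: self.stride] = dy
        dyp, _, _ = _patches3(dyz, 1)
        return (dyp @ self._w_flipped()).reshape(b, h, w, c)


class UpConv2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / c_in)
        self.w = Param(rng.normal(0.0, scale, size=(c_in, 4 * c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True, update_stats=True):
        b, h, w, c = x.shape
        t = (x.reshape(b * h * w, c) @ self.w.data).reshape(b, h, w, 2, 2, self.c_out)
        y = np.ascontiguousarray(t.transpose(0, 1, 3, 2, 4, 5)).reshape(
            b, 2 * h, 2 * w, self.c_out
        )
        y += self.b.data
        return y, (x,)

    def backward(self, dy, cache):
        (x,) = cache
        b, h, w, c = x.shape
        d6 = np.ascontiguousarray(
            dy.reshape(b, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(b * h * w, 4 * self.c_out)
        xf = x.reshape(b * h * w, c)
        self.w.grad += xf.T @ d6
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return (d6 @ self.w.data.T).reshape(b, h, w, c)


class Linear(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        bias_init: float = 0.0,
    ):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        # a slightly positive bias_init keeps pre-ReLU units alive at the
        # start of training (dead bottleneck units cannot recover)
        self.b = Param(np.full(n_out, bias_init))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True, update_stats=True):
        return x @ self.w.data + self.b.data, (x,)

    def backward(self, dy, cache):
        (x,) = cache
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.data.T


# ---------------------------------------------------------------------------
# Normalization and activations
# ---------------------------------------------------------------------------

class _BatchNorm(Layer):
    """Normalize over all axes but the last (the feature/channel axis)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features, dtype=F32)
        self.running_var = np.ones(n_features, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True, update_stats=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if update_stats:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(F32)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean) * inv
        y = self.gamma.data * xhat + self.beta.data
        return y.astype(F32), (xhat, inv, train)

    def backward(self, dy, cache):
        xhat, inv, train = cache
        axes = tuple(range(dy.ndim - 1))
        self.beta.grad += dy.sum(axis=axes)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        g = self.gamma.data * inv
        if not train:
            return (dy * g).astype(F32)
        dmean = dy.mean(axis=axes)
        dproj = (dy * xhat).mean(axis=axes)
        return (g * (dy - dmean - xhat * dproj)).astype(F32)


class BatchNorm2d(_BatchNorm):
    """Per-channel batch norm for (B, H, W, C) activations."""


class BatchNorm1d(_BatchNorm):
    """Per-feature batch norm for (B, F) activations."""


class ReLU(Layer):
    def forward(self, x, train=True, update_stats=True):
        mask = x > 0
        return x * mask, (mask,)

    def backward(self, dy, cache):
        (mask,) = cache
        return dy * mask


class Sigmoid(Layer):
    def forward(self, x, train=True, update_stats=True):
        y = 1.0 / (1.0 + np.exp(-x))
        return y.astype(F32), (y,)

    def backward(self, dy, cache):
        (y,) = cache
        return (dy * y * (1.0 - y)).astype(F32)


class Flatten(Layer):
    def forward(self, x, train=True, update_stats=True):
        return x.reshape(x.shape[0], -1), (x.shape,)

    def backward(self, dy, cache):
        (shape,) = cache
        return dy.reshape(shape)


class Reshape(Layer):
    """(B, prod(shape)) <-> (B, *shape)."""

    def __init__(self, shape: Tuple[int, ...]):
        self.shape = shape

    def forward(self, x, train=True, update_stats=True):
        return x.reshape((x.shape[0],) + self.shape), (x.shape,)

    def backward(self, dy, cache):
        (shape,) = cache
        return dy.reshape(shape)
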