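"""Minimal NumPy neural-network layers for the desk-scale models.

Implements exactly what the two miniature estimators need: 2-D convolution
(kernel 1 or 3, stride 1, zero padding "same"), ReLU, sigmoid, 2x2 max
pooling, 2x nearest-neighbour upsampling, channel concatenation, global
average pooling, inverted dropout, a dense layer, and the Adam optimizer.
Everything is deterministic given a seeded ``numpy.random.Generator``;
gradients are hand-derived and verified by finite differences in the test
suite.

Tensors are ``(N, C, H, W)`` float64 arrays.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "Conv2D",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "Upsample2",
    "GlobalAvgPool",
    "Dropout",
    "Dense",
    "Adam",
    "count_parameters",
]


class Layer:
    """Base layer: forward caches what backward needs; params/grads aligned."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """k x k convolution (k in {1, 3}), stride 1, zero-padded to same size."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        if k not in (1, 3):
            raise InvalidParameterError(f"kernel size must be 1 or 3, got {k}")
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.k = k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        self._shape = (H, W)
        out = np.empty((N, self.W.shape[0], H, W))
        out[:] = self.b[None, :, None, None]
        for i in range(self.k):
            for j in range(self.k):
                out += np.einsum(
                    "nchw,oc->nohw",
                    xp[:, :, i : i + H, j : j + W],
                    self.W[:, :, i, j],
                    optimize=True,
                )
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H, W = self._shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + H, j : j + W] += np.einsum(
                    "nohw,oc->nchw", dy, self.W[:, :, i, j], optimize=True
                )
                self.dW[:, :, i, j] = np.einsum(
                    "nohw,nchw->oc", dy, xp[:, :, i : i + H, j : j + W], optimize=True
                )
        self.db[:] = dy.sum(axis=(0, 2, 3))
        p = self.k // 2
        return dxp[:, :, p : p + H, p : p + W] if p else dxp

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x):
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise InvalidParameterError(f"pooling needs even spatial dims, got {H}x{W}")
        r = x.reshape(N, C, H // 2, 2, W // 2, 2)
        self._x = x
        out = r.max(axis=(3, 5))
        self._mask = x == np.repeat(np.repeat(out, 2, axis=2), 2, axis=3)
        # break ties: keep only first max in each 2x2 block
        m = self._mask.reshape(N, C, H // 2, 2, W // 2, 2)
        flat = m.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        first = np.argmax(flat, axis=-1)
        keep = np.zeros_like(flat)
        np.put_along_axis(keep, first[..., None], 1.0, axis=-1)
        self._mask = (
            keep.reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )
        return out

    def backward(self, dy):
        return self._mask * np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (H * W)


class Dropout(Layer):
    """Inverted dropout on (N, C) features; active only when train=True."""

    def __init__(self, keep: float, rng: np.random.Generator):
        if not 0 < keep <= 1:
            raise InvalidParameterError(f"dropout keep fraction must be in (0, 1], got {keep}")
        self.keep = keep
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.keep >= 1.0:
            self._m = None
            return x
        self._m = (self.rng.random(x.shape) < self.keep) / self.keep
        return x * self._m

    def backward(self, dy):
        return dy if self._m is None else dy * self._m


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise InvalidParameterError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def count_parameters(layers_or_model) -> int:
    """Total number of trainable scalars in a model or list of layers."""
    layers = getattr(layers_or_model, "layers", layers_or_model)
    return int(sum(p.size for layer in layers for p in layer.params()))
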