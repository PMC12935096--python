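"""Minimal NumPy neural-network engine for 3D convolutional models.

Implements exactly the layer set the fragment-prediction architecture needs:
valid 3D convolution, batch normalization, ReLU, max pooling, global average
pooling, dropout, fully connected layers and a sigmoid head, each with a
hand-derived backward pass, plus an Adam optimizer. All math is float32 and
BLAS-backed: convolutions are expressed as 27 offset-wise GEMMs (one per
kernel tap), which keeps peak memory low — no materialized im2col buffer —
while running at matrix-multiply throughput.

Layers follow a uniform contract: ``forward(x, train=...)`` caches what the
backward pass needs; ``backward(dy)`` returns the input gradient and fills
``grads`` for parametrised layers.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

F32 = np.float32


class Layer:
    """Base layer; parameter-free layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x3: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (S, C*k^3) column matrix of all valid kxkxk windows."""
    from numpy.lib.stride_tricks import sliding_window_view

    sw = sliding_window_view(x3, (k, k, k), axis=(1, 2, 3))
    C = x3.shape[0]
    return sw.transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, C * k**3)


def _conv3d_valid(x: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Valid-mode 3D convolution (cross-correlation) via per-example im2col GEMM.

    x: (B, C, D, H, W); weight: (O, C, k, k, k) -> (B, O, D-k+1, H-k+1, W-k+1)
    """
    B, C, D, H, W = x.shape
    O, _, k, _, _ = weight.shape
    Do, Ho, Wo = D - k + 1, H - k + 1, W - k + 1
    w2 = weight.reshape(O, -1)
    y = np.empty((B, O, Do, Ho, Wo), dtype=F32)
    for b in range(B):
        y[b] = (w2 @ _im2col(x[b], k).T).reshape(O, Do, Ho, Wo)
    return y


class Conv3d(Layer):
    """3D convolution, kernel k, stride 1, no padding.

    Columns are rebuilt (not cached) in the backward pass: with ~55 MB of
    column matrix per 64-channel example, caching across six conv layers and
    a 16-example batch would dominate memory.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        fan_in = in_channels * kernel**3
        bound = 1.0 / np.sqrt(fan_in)
        self.params["weight"] = rng.uniform(
            -bound, bound, size=(out_channels, in_channels, kernel, kernel, kernel)
        ).astype(F32)
        self.params["bias"] = rng.uniform(-bound, bound, size=out_channels).astype(F32)

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        self._x = x
        y = _conv3d_valid(x, self.params["weight"])
        y += self.params["bias"][None, :, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w, k = self._x, self.params["weight"], self.k
        B, C = x.shape[:2]
        O, _, Do, Ho, Wo = (w.shape[0],) + dy.shape[1:]
        O = dy.shape[1]
        w2 = w.reshape(O, -1)
        self.grads["bias"] = dy.sum(axis=(0, 2, 3, 4))
        dw2 = np.zeros_like(w2, dtype=np.float64)
        dx = np.zeros_like(x)
        for b in range(B):
            cols = _im2col(x[b], k)  # (S, C k^3)
            dyb = dy[b].reshape(O, -1)  # (O, S)
            dw2 += dyb @ cols
            dcols = (dyb.T @ w2).reshape(Do, Ho, Wo, C, k, k, k)
            for a, bb, c in itertools.product(range(k), repeat=3):
                dx[b, :, a : a + Do, bb : bb + Ho, c : c + Wo] += np.moveaxis(
                    dcols[:, :, :, :, a, bb, c], 3, 0
                )
        self.grads["weight"] = dw2.astype(F32).reshape(w.shape)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (B, C, *spatial) or (B, C)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=F32)
        self.params["beta"] = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def _shape(self, x: np.ndarray) -> tuple:
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(F32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._cache = (xhat, inv, axes, sh)
        return (self.params["gamma"].reshape(sh) * xhat + self.params["beta"].reshape(sh)).astype(
            F32
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes, sh = self._cache
        n = dy.size / dy.shape[1]
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"].reshape(sh)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(sh)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(sh)
        ) * inv.reshape(sh)
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0.0))


class MaxPool3d(Layer):
    """Max pooling with kernel = stride (spatial dims must divide evenly)."""

    def __init__(self, kernel: int = 2):
        super().__init__()
        self.k = kernel

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        B, C, D, H, W = x.shape
        k = self.k
        xr = x.reshape(B, C, D // k, k, H // k, k, W // k, k)
        y = xr.max(axis=(3, 5, 7))
        # gradient is routed to every argmax position (ties share; rare in floats)
        self._mask = xr == y[:, :, :, None, :, None, :, None]
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self._mask * dy[:, :, :, None, :, None, :, None]
        return dx.reshape(self._shape).astype(F32)


class GlobalAvgPool(Layer):
    """(B, C, D, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, D, H, W = self._shape
        scale = F32(1.0 / (D * H * W))
        return np.broadcast_to((dy * scale)[:, :, None, None, None], self._shape).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.params["weight"] = rng.uniform(-bound, bound, size=(out_features, in_features)).astype(
            F32
        )
        self.params["bias"] = rng.uniform(-bound, bound, size=out_features).astype(F32)

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["weight"] = dy.T @ self._x
        self.grads["bias"] = dy.sum(axis=0)
        return (dy @ self.params["weight"]).astype(F32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        # numerically stable piecewise logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * self._y * (1.0 - self._y)).astype(F32)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self) -> Iterator[tuple[str, Layer, str]]:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"layer{i}.{name}", layer, name


class Adam:
    """Adam optimizer with the conventional defaults."""

    def __init__(
        self,
        model: Sequential,
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for key, layer, name in self.model.named_params():
            g = layer.grads[name].astype(np.float64)
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
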