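"""Minimal NumPy neural-network layer library with explicit backpropagation.

Implements exactly the layer vocabulary the recurrence networks need —
stride-1 same-padded 2D convolution, non-overlapping max pooling, shared-slope
PReLU, 2D batch normalization, global average pooling and dense layers —
together with mini-batch SGD with momentum and a binary cross-entropy head.

Performance notes: activations are float32 in channels-last (N, H, W, C)
layout, which keeps pooling and batch-norm free of transposes. Convolutions
gather their patch matrix with a small numba kernel and hand the contraction
to BLAS; the input gradient is computed as one GEMM against the kernel
followed by a col2im scatter-add (a transposed convolution). Pooling runs in
fused numba kernels, and large scratch arrays are reused across SGD steps.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "MaxPool2d",
    "PReLU",
    "BatchNorm2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "SGD",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    # softplus(z) - y*z, evaluated stably
    loss = float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.reshape(np.shape(logits)).astype(np.float32)


class Param:
    """A trainable tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "velocity", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer; forward caches whatever backward needs when asked to."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@njit(cache=True)
def _gather_patches(xp, col, k):  # pragma: no cover - compiled
    # xp: (n, h+k-1, w+k-1, c) padded input; col: (n, h, w, k*k, c)
    n, h, w, kk, c = col.shape
    for i in range(n):
        for r in range(h):
            for cc in range(w):
                j = 0
                for a in range(k):
                    for b in range(k):
                        for ch in range(c):
                            col[i, r, cc, j, ch] = xp[i, r + a, cc + b, ch]
                        j += 1


@njit(cache=True)
def _scatter_add_patches(dxp, q, k):  # pragma: no cover - compiled
    # reverse of _gather_patches: dxp[i, r+a, c+b, ch] += q[i, r, c, j, ch]
    n, h, w, kk, c = q.shape
    for i in range(n):
        for r in range(h):
            for cc in range(w):
                j = 0
                for a in range(k):
                    for b in range(k):
                        for ch in range(c):
                            dxp[i, r + a, cc + b, ch] += q[i, r, cc, j, ch]
                        j += 1


@njit(cache=True)
def _pool_fwd(x, out, k):  # pragma: no cover - compiled
    n, ho, wo, c = out.shape
    for i in range(n):
        for r in range(ho):
            for q in range(wo):
                for ch in range(c):
                    out[i, r, q, ch] = x[i, r * k, q * k, ch]
                for a in range(k):
                    for b in range(k):
                        if a == 0 and b == 0:
                            continue
                        for ch in range(c):
                            v = x[i, r * k + a, q * k + b, ch]
                            if v > out[i, r, q, ch]:
                                out[i, r, q, ch] = v


@njit(cache=True)
def _pool_bwd(x, out, dy, dx, cnt, k):  # pragma: no cover - compiled
    # gradient split equally among positions attaining the window maximum
    n, ho, wo, c = out.shape
    for i in range(n):
        for r in range(ho):
            for q in range(wo):
                for ch in range(c):
                    cnt[ch] = 0.0
                for a in range(k):
                    for b in range(k):
                        for ch in range(c):
                            if x[i, r * k + a, q * k + b, ch] == out[i, r, q, ch]:
                                cnt[ch] += 1.0
                for a in range(k):
                    for b in range(k):
                        for ch in range(c):
                            if x[i, r * k + a, q * k + b, ch] == out[i, r, q, ch]:
                                dx[i, r * k + a, q * k + b, ch] += dy[i, r, q, ch] / cnt[ch]


class _BufferPool:
    """Reusable scratch arrays keyed by name; avoids re-allocating (and
    page-faulting) hundreds of MB per SGD step."""

    __slots__ = ("bufs",)

    def __init__(self) -> None:
        self.bufs: dict = {}

    def get(self, name: str, shape: tuple, zero: bool = False) -> np.ndarray:
        buf = self.bufs.get(name)
        if buf is None or buf.shape != shape:
            buf = np.zeros(shape, dtype=np.float32) if zero else np.empty(
                shape, dtype=np.float32)
            self.bufs[name] = buf
        elif zero:
            buf[:] = 0
        return buf


def _im2col(x: np.ndarray, k: int, pad_lo: int, pad_hi: int,
            pool: _BufferPool, tag: str) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix for stride-1 same convolution."""
    n, h, w, c = x.shape
    xp = pool.get(tag + ".pad", (n, h + k - 1, w + k - 1, c), zero=True)
    xp[:, pad_lo:pad_lo + h, pad_lo:pad_lo + w, :] = x
    col = pool.get(tag + ".col", (n, h, w, k * k, c))
    _gather_patches(xp, col, k)
    return col.reshape(n * h * w, k * k * c)


class Conv2d(Layer):
    """Stride-1 2D convolution with 'same' output size.

    Even kernels pad asymmetrically: ``(k-1)//2`` before, the remainder after,
    so every kernel size in {2,...,6} maps HxW to HxW and the kernel variants
    are drop-in interchangeable.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, needs_input_grad: bool = True) -> None:
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.pad_lo = (kernel - 1) // 2
        self.pad_hi = kernel - 1 - self.pad_lo
        fan_in = in_channels * kernel * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Param(
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel, kernel)),
            "conv.weight")
        self.bias = Param(rng.uniform(-bound, bound, out_channels), "conv.bias")
        self.needs_input_grad = needs_input_grad
        self._pool = _BufferPool()
        self._col: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _wflat(self) -> np.ndarray:
        # (k*k*cin, cout), taps ordered as in _im2col
        return np.ascontiguousarray(
            self.weight.value.transpose(2, 3, 1, 0).reshape(-1, self.cout))

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        col = _im2col(x, self.k, self.pad_lo, self.pad_hi, self._pool, "fwd")
        y = col @ self._wflat()
        y += self.bias.value
        if train or cache:
            self._col, self._shape = col, x.shape
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        dyf = dy.reshape(n * h * w, self.cout)
        dwf = self._col.T @ dyf  # (k*k*cin, cout)
        self._col = None
        self.weight.grad = np.ascontiguousarray(
            dwf.reshape(self.k, self.k, self.cin, self.cout).transpose(3, 2, 0, 1))
        self.bias.grad = dyf.sum(axis=0)
        if not self.needs_input_grad:
            return np.zeros(self._shape, dtype=np.float32)
        # dx via col2im: one GEMM against the weight, then k*k shifted
        # block-adds onto the padded input gradient (transposed convolution)
        k = self.k
        wq = np.ascontiguousarray(
            self.weight.value.transpose(0, 2, 3, 1).reshape(self.cout, -1))
        q = (dyf @ wq).reshape(n, h, w, k * k, self.cin)
        dxp = self._pool.get("bwd.pad", (n, h + k - 1, w + k - 1, self.cin),
                             zero=True)
        _scatter_add_patches(dxp, q, k)
        return np.ascontiguousarray(
            dxp[:, self.pad_lo:self.pad_lo + h, self.pad_lo:self.pad_lo + w, :])


class MaxPool2d(Layer):
    """k x k max pooling with stride k; trailing rows/cols beyond the last
    full window are dropped (floor semantics).

    The gradient of a window is split equally among the positions attaining
    the maximum, a deterministic subgradient that matters only for exactly
    tied values (e.g. constant padding regions).
    """

    def __init__(self, k: int) -> None:
        self.k = k
        self._pool = _BufferPool()
        self._x: np.ndarray | None = None
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = False) -> np.ndarray:
        k = self.k
        n, h, w, c = x.shape
        x = np.ascontiguousarray(x)
        out = np.empty((n, h // k, w // k, c), dtype=np.float32)
        _pool_fwd(x, out, k)
        if train or cache:
            self._x, self._out = x, out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, out = self._x, self._out
        n, h, w, c = x.shape
        dx = self._pool.get("dx", (n, h, w, c), zero=True)
        cnt = np.empty(c, dtype=np.float32)
        _pool_bwd(x, out, np.ascontiguousarray(dy), dx, cnt, self.k)
        self._x = self._out = None
        return dx


class PReLU(Layer):
    """Parametric ReLU with one shared learnable negative slope."""

    def __init__(self, init: float = 0.25) -> None:
        self.alpha = Param(np.array([init], dtype=np.float32), "prelu.alpha")
        self._neg: np.ndarray | None = None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.alpha]

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = False) -> np.ndarray:
        neg = x < 0
        out = np.where(neg, self.alpha.value[0] * x, x).astype(np.float32)
        if train or cache:
            self._neg, self._x = neg, x
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        neg, x = self._neg, self._x
        self.alpha.grad = np.array([float(np.sum(dy[neg] * x[neg]))], dtype=np.float32)
        dx = np.where(neg, self.alpha.value[0] * dy, dy).astype(np.float32)
        self._neg = self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine parameters.

    Training uses batch statistics and updates exponential running moments
    (momentum 0.1, unbiased variance in the running buffer); inference uses
    the running moments, which makes prediction deterministic. Channels are
    the last axis.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.c = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = x.shape[0] * x.shape[1] * x.shape[2]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            unbiased = var * m / max(m - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        scale = self.gamma.value * inv
        out = x * scale + (self.beta.value - mu * scale)
        if train or cache:
            # batch statistics couple the gradient across the batch only in
            # training mode; with running statistics BN is a fixed affine map
            xhat = (x - mu) * inv
            self._cache = (xhat, inv, train)
        return out.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, coupled = self._cache
        dgamma = np.sum(dy * xhat, axis=(0, 1, 2))
        dbeta = np.sum(dy, axis=(0, 1, 2))
        self.gamma.grad = dgamma.astype(np.float32)
        self.beta.grad = dbeta.astype(np.float32)
        g = self.gamma.value * inv
        if coupled:
            m = dy.shape[0] * dy.shape[1] * dy.shape[2]
            dx = g * (dy - (dbeta + xhat * dgamma) / m)
        else:
            dx = g * dy
        self._cache = None
        return dx.astype(np.float32)


class GlobalAvgPool(Layer):
    """(N,H,W,C) -> (N,C): mean over the spatial axes."""

    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = False) -> np.ndarray:
        if train or cache:
            self._shape = x.shape
        return x.mean(axis=(1, 2)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w),
                               (n, h, w, c)).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Param(rng.uniform(-bound, bound, (out_features, in_features)),
                            "fc.weight")
        self.bias = Param(rng.uniform(-bound, bound, out_features), "fc.bias")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = False) -> np.ndarray:
        if train or cache:
            self._x = x
        return (x @ self.weight.value.T + self.bias.value).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad = dy.T @ self._x
        self.bias.grad = dy.sum(axis=0)
        dx = dy @ self.weight.value
        self._x = None
        return dx.astype(np.float32)


class Sequential:
    """An ordered layer stack producing a logit; sigmoid lives in the loss/predict."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, cache=cache)
        return x

    def forward_upto(self, x: np.ndarray, stop: int, train: bool = False,
                     cache: bool = False) -> np.ndarray:
        """Forward through layers [0, stop); returns that activation."""
        for layer in self.layers[:stop]:
            x = layer.forward(x, train=train, cache=cache)
        return x

    def forward_from(self, x: np.ndarray, start: int, train: bool = False,
                     cache: bool = False) -> np.ndarray:
        for layer in self.layers[start:]:
            x = layer.forward(x, train=train, cache=cache)
        return x

    def backward(self, dy: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Backpropagate; returns the gradient flowing into layer ``stop_at``
        (i.e. w.r.t. the output of layer ``stop_at - 1``)."""
        for layer in reversed(self.layers[stop_at:]):
            dy = layer.backward(dy)
        return dy

    def count_parameters(self) -> int:
        return sum(p.size for p in self.params())


class SGD:
    """Stochastic gradient descent with classical momentum:
    v <- mu*v + g;  p <- p - lr*v."""

    def __init__(self, params: list[Param], momentum: float = 0.5) -> None:
        self.params = params
        self.momentum = momentum

    def step(self, lr: float) -> None:
        for p in self.params:
            p.velocity = self.momentum * p.velocity + p.grad
            p.value -= np.float32(lr) * p.velocity
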