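"""Minimal numpy neural-network layers with explicit backpropagation.

Just enough machinery for the drowsiness temporal CNN: 1-D convolution
(same-length, zero padding) via im2col, max pooling, batch normalization,
ReLU, inverted dropout, dense layers and Adam.  Each layer caches what its
backward pass needs; parameters are ``Param`` objects (value + grad) so an
optimizer can walk a flat list.  Everything is float32.

The backward passes are verified against central-difference numeric
gradients in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1D",
    "MaxPool1D",
    "BatchNorm1D",
    "ReLU",
    "Dropout",
    "Dense",
    "Adam",
]

F32 = np.float32


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def train_mode(self, flag: bool) -> None:  # noqa: ARG002 - stateless layers
        pass


class Conv1D(Layer):
    """Temporal convolution, stride 1, zero padding preserving length.

    Input/output layout is (batch, channels, length).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd so padding preserves length")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init for the ReLU that follows
        # weight column j * c_in + c multiplies channel c at kernel offset j
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in * kernel)))
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (N, C, L) -> (C*K, N*L): kernel offsets stacked as channel blocks,
        # channel-major so every pass is a single large GEMM
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        xpt = np.ascontiguousarray(xp.transpose(1, 0, 2))  # (C, N, Lp)
        cols = np.empty((c * self.kernel, n, length), dtype=F32)
        for j in range(self.kernel):
            cols[j * c : (j + 1) * c] = xpt[:, :, j : j + length]
        return cols.reshape(c * self.kernel, n * length)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, length = x.shape
        cols = self._im2col(x.astype(F32))
        y = self.w.value @ cols  # (C_out, N*L)
        self._cols, self._shape = cols, x.shape
        y = y.reshape(self.c_out, n, length) + self.b.value[:, None, None]
        return np.ascontiguousarray(y.transpose(1, 0, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dy2 = np.ascontiguousarray(dy.transpose(1, 0, 2), dtype=F32).reshape(self.c_out, -1)
        self.w.grad += dy2 @ self._cols.T
        self.b.grad += dy2.sum(axis=1)
        dcols = (self.w.value.T @ dy2).reshape(self.kernel, c, n, length)
        dxpt = np.zeros((c, n, length + 2 * self.pad), dtype=F32)
        for j in range(self.kernel):
            dxpt[:, :, j : j + length] += dcols[j]
        return dxpt[:, :, self.pad : self.pad + length].transpose(1, 0, 2)


class MaxPool1D(Layer):
    """Non-overlapping max pooling (kernel == stride)."""

    def __init__(self, kernel: int = 3):
        self.kernel = kernel
        self._argmax: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        if length % self.kernel:
            raise ValueError(f"length {length} not divisible by pool kernel {self.kernel}")
        xr = x.reshape(n, c, length // self.kernel, self.kernel)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dxr = np.zeros((n, c, length // self.kernel, self.kernel), dtype=F32)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None].astype(F32), axis=3)
        return dxr.reshape(n, c, length)


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length).

    Running statistics (momentum 0.1) are frozen at inference.  Accepts
    (N, C, L) or (N, C) input.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.training = True
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def train_mode(self, flag: bool) -> None:
        self.training = flag

    def _axes(self, x: np.ndarray) -> tuple:
        return (0,) if x.ndim == 2 else (0, 2)

    def _expand(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v[None, :] if ndim == 2 else v[None, :, None]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(F32)
        axes = self._axes(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(inv, x.ndim)
        self._cache = (xhat, inv, axes, x.ndim)
        return self._expand(self.gamma.value, x.ndim) * xhat + self._expand(self.beta.value, x.ndim)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes, ndim = self._cache
        dy = dy.astype(F32)
        m = np.prod([dy.shape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self._expand(self.gamma.value, ndim)
        if self.training:
            dxhat = dy * g
            term = dxhat - dxhat.mean(axis=axes, keepdims=True) - xhat * (dxhat * xhat).sum(
                axis=axes, keepdims=True
            ) / m
            return term * self._expand(inv, ndim)
        return dy * g * self._expand(inv, ndim)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng
        self.training = True
        self._mask: np.ndarray | None = None

    def train_mode(self, flag: bool) -> None:
        self.training = flag

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Dense(Layer):
    """Fully connected layer on (batch, features)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(F32)
        return self._x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(F32)
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
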