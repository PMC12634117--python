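"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly what the ECG models need: 1-D convolution (im2col GEMM),
batch normalization, ReLU, inverted dropout, global average pooling, dense
layers, residual blocks, and Adam. Forward passes cache what the backward
pass needs; ``backward`` must be called with the same training flag the
forward pass used. All parameters are float32.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution over (N, C, L) with 'same'-style zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in * kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel, self.stride, self.c_in = kernel, stride, c_in
        self.pad = kernel // 2

    def params(self):
        return [self.w, self.b]

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        # xp: (N, C, Lp) -> (N, C*k, Lo)
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        windows = windows[:, :, ::self.stride, :]          # (N, C, Lo, k)
        n, c, lo, k = windows.shape
        return windows.transpose(0, 1, 3, 2).reshape(n, c * k, lo)

    def forward(self, x, train=False):
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = self._im2col(np.ascontiguousarray(xp, dtype=np.float32))
        self._cols, self._in_len = cols, length
        lo = cols.shape[2]
        flat = cols.transpose(1, 0, 2).reshape(cols.shape[1], n * lo)
        y = (self.w.value @ flat).reshape(-1, n, lo).transpose(1, 0, 2)
        return y + self.b.value[None, :, None]

    def backward(self, dout):
        n, c_out, lo = dout.shape
        cols = self._cols
        dflat = dout.transpose(1, 0, 2).reshape(c_out, n * lo)
        colflat = cols.transpose(1, 0, 2).reshape(cols.shape[1], n * lo)
        self.w.grad += dflat @ colflat.T
        self.b.grad += dout.sum(axis=(0, 2))
        dcols = (self.w.value.T @ dflat).reshape(cols.shape[1], n, lo)
        dcols = dcols.transpose(1, 0, 2).reshape(n, self.c_in, self.kernel, lo)
        lp = self._in_len + 2 * self.pad
        dxp = np.zeros((n, self.c_in, lp), dtype=np.float32)
        idx = np.arange(lo) * self.stride
        for j in range(self.kernel):
            np.add.at(dxp, (slice(None), slice(None), idx + j), dcols[:, :, j, :])
        return dxp[:, :, self.pad:self.pad + self._in_len]


class BatchNorm1d(Layer):
    """Batch normalization over (N, C, L) or (N, C), normalizing per channel."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, train=False):
        axes, shape = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape, train,
                       np.prod([x.shape[a] for a in axes]))
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dout):
        xhat, inv, axes, shape, train, m = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shape)
        if not train:
            return dxhat * inv.reshape(shape)
        term = (dxhat - dxhat.mean(axis=axes).reshape(shape)
                - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape))
        return term * inv.reshape(shape)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    """(N, C, L) -> (N, C) mean over time."""

    def forward(self, x, train=False):
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._len, axis=2) / self._len


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock(Layer):
    """conv-BN-ReLU-dropout-conv-BN plus a (possibly projected) shortcut."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 dropout: float, rng: np.random.Generator):
        self.main = Sequential(
            Conv1d(c_in, c_out, kernel, stride, rng=rng),
            BatchNorm1d(c_out),
            ReLU(),
            Dropout(dropout, rng),
            Conv1d(c_out, c_out, kernel, 1, rng=rng),
            BatchNorm1d(c_out),
        )
        if c_in != c_out or stride != 1:
            self.shortcut: Layer | None = Sequential(
                Conv1d(c_in, c_out, 1, stride, rng=rng), BatchNorm1d(c_out))
        else:
            self.shortcut = None

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x, train=False):
        h = self.main.forward(x, train=train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        out = h + s
        self._mask = out > 0
        return out * self._mask

    def backward(self, dout):
        dout = dout * self._mask
        dx = self.main.backward(dout)
        if self.shortcut is None:
            return dx + dout
        return dx + self.shortcut.backward(dout)


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.value
            p.value -= (self.lr * update).astype(np.float32)


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s
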