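"""Minimal deterministic neural-network engine.

Small, CPU-only building blocks (dense and 3x3 convolution layers, pointwise
activations, global average pooling) with hand-written reverse-mode gradients
and an Adam optimiser.  Everything is plain ``float32`` NumPy; given the same
seed and inputs every forward/backward pass is bit-reproducible, which the
pipeline relies on for checkpoint restoration and end-to-end determinism.

Conventions: image tensors are NCHW; feature matrices are (batch, features).
A layer caches whatever it needs for the backward pass on ``forward`` and
consumes that cache on ``backward``, so forward/backward calls must be paired.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Dense",
    "Conv2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "GlobalAvgPool2d",
    "Sequential",
    "Adam",
]


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine layer ``x @ W + b`` with He-normal initialisation."""

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / fan_in)
        self.W = Parameter(rng.normal(0.0, std, size=(fan_in, fan_out)))
        self.b = Parameter(np.zeros(fan_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = float(alpha)

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Conv2d(Layer):
    """3x3 convolution (NCHW) via patch-matrix multiplication.

    Padding 1; stride 1 or 2.  The patch matrix is built from nine strided
    slices, which keeps both directions fully vectorised.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, ksize: int = 3, pad: int = 1):
        self.cin, self.cout = cin, cout
        self.k, self.stride, self.pad = ksize, stride, pad
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        self.W = Parameter(rng.normal(0.0, std, size=(cin * ksize * ksize, cout)))
        self.b = Parameter(np.zeros(cout))

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        b, c = xp.shape[:2]
        k, s = self.k, self.stride
        cols = np.empty((b, c, k * k, oh, ow), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, ki * k + kj] = xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s]
        return cols

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._im2col(xp, oh, ow)
        mat = cols.reshape(b, c * k * k, oh * ow).transpose(0, 2, 1).reshape(-1, c * k * k)
        out = mat @ self.W.value + self.b.value
        self._cache = (mat, x.shape, oh, ow)
        return out.reshape(b, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        mat, xshape, oh, ow = self._cache
        b, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        gm = grad.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.W.grad += mat.T @ gm
        self.b.grad += gm.sum(axis=0)
        dcols = (gm @ self.W.value.T).reshape(b, oh * ow, c * k * k)
        dcols = dcols.transpose(0, 2, 1).reshape(b, c, k * k, oh, ow)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += dcols[:, :, ki * k + kj]
        return dxp[:, :, p:p + h, p:p + w]


class GlobalAvgPool2d(Layer):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        g = grad[:, :, None, None] / (h * w)
        return np.broadcast_to(g, self._shape).astype(np.float32).copy()


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- weight snapshots (cloning, checkpoints, best-epoch restoration) ----
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(state):
            raise ValueError("state does not match network parameters")
        for p, v in zip(own, state):
            if p.value.shape != v.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = v


class Adam:
    """Adam optimiser over an explicit parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
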