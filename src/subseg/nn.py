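"""Minimal NumPy neural-network primitives with explicit backprop.

Implements exactly what the three-path patch classifier needs: 2-D
convolution (same padding, optional stride) via im2col matrix products,
rectified-linear units, dense layers, a fused softmax/cross-entropy head and
the Adam optimizer.  Gradients are analytic and are verified against finite
differences in the test suite.

All parameters are float32; forward passes cache what the backward pass
needs.  There is no autograd: each layer exposes ``forward`` / ``backward``
and owns its parameter and gradient arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "Dense", "softmax", "cross_entropy_grad", "Adam", "he_uniform"]


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D:
    """2-D convolution, NCHW layout, 'same' zero padding, square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = in_channels, out_channels, kernel_size, stride
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.W = he_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def out_size(self, n: int) -> int:
        p = self.k // 2
        return (n + 2 * p - self.k) // self.stride + 1

    def _cols(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        return win[:, :, ::self.stride, ::self.stride]  # (N,Cin,Ho,Wo,k,k)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n = x.shape[0]
        cols = self._cols(x)
        ho, wo = cols.shape[2], cols.shape[3]
        flat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, self.cin * self.k * self.k)
        wmat = self.W.reshape(self.cout, -1)
        out = flat @ wmat.T + self.b
        out = out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        if train:
            self._cache = (x.shape, flat, (n, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, flat, (n, ho, wo) = self._cache
        dflat_out = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.dW[...] = (dflat_out.T @ flat).reshape(self.W.shape)
        self.db[...] = dflat_out.sum(axis=0)
        wmat = self.W.reshape(self.cout, -1)
        dcols = (dflat_out @ wmat).reshape(n, ho, wo, self.cin, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, self.cin, x_shape[2] + 2 * p, x_shape[3] + 2 * p), dtype=np.float32)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + x_shape[2], p:p + x_shape[3]]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dense:
    """Fully connected layer y = x W^T + b."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = he_uniform(rng, (out_features, in_features), in_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = len(labels)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    """Adam optimizer over an explicit list of (param, grad) pairs."""

    def __init__(self, params_and_grads, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(params_and_grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
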