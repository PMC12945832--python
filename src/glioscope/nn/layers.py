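"""Batched NHWC layers with analytic backward passes.

Everything is plain numpy; each layer caches what its backward pass needs
and accumulates parameter gradients in ``self.grads``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "DepthwiseConv2D",
    "ReLU",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "SqueezeExcite",
    "softmax",
    "sigmoid",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class; stateless layers leave params/grads empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(h: int, w: int, k: int, stride: int):
    ho = -(-h // stride)
    wo = -(-w // stride)
    ph = max((ho - 1) * stride + k - h, 0)
    pw = max((wo - 1) * stride + k - w, 0)
    return ho, wo, (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)


class Conv2D(Layer):
    """k x k convolution, same padding.  W: (k, k, C_in, C_out).

    Implemented as k*k shifted matmuls, which keeps peak memory at one
    feature map and lets BLAS do the heavy lifting.
    """

    def __init__(self, kernel: int, c_in: int, c_out: int, stride: int = 1):
        super().__init__()
        self.kernel, self.c_in, self.c_out, self.stride = kernel, c_in, c_out, stride
        self.params = {
            "W": np.zeros((kernel, kernel, c_in, c_out)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, training=False):
        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        k, s = self.kernel, self.stride
        n, h, w, _ = x.shape
        ho, wo, (pt, pb), (pl, pr) = _same_pad(h, w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        W = self.params["W"]
        y = np.zeros((n, ho, wo, self.c_out), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                y += xp[:, i : i + s * ho : s, j : j + s * wo : s, :] @ W[i, j]
        self._cache = (xp, (pt, pl), x.shape, (ho, wo))
        return y + self.params["b"]

    def backward(self, dout):
        xp, (pt, pl), x_shape, (ho, wo) = self._cache
        k, s = self.kernel, self.stride
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros(xp.shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, i : i + s * ho : s, j : j + s * wo : s, :]
                dW[i, j] = np.tensordot(xp[sl], dout, axes=([0, 1, 2], [0, 1, 2]))
                dxp[sl] += dout @ W[i, j].T
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        _, h, w, _ = x_shape
        return dxp[:, pt : pt + h, pl : pl + w, :]


class DepthwiseConv2D(Layer):
    """Per-channel k x k convolution, same padding.  W: (k, k, C)."""

    def __init__(self, kernel: int, channels: int, stride: int = 1):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd-sized")
        self.kernel, self.channels, self.stride = kernel, channels, stride
        self.params = {"W": np.zeros((kernel, kernel, channels)), "b": np.zeros(channels)}

    def forward(self, x, training=False):
        if x.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[-1]}")
        k, s = self.kernel, self.stride
        n, h, w, _ = x.shape
        ho, wo, (pt, pb), (pl, pr) = _same_pad(h, w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        W = self.params["W"]
        y = np.zeros((n, ho, wo, self.channels), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                y += xp[:, i : i + s * ho : s, j : j + s * wo : s, :] * W[i, j]
        self._cache = (xp, (pt, pl), x.shape, (ho, wo))
        return y + self.params["b"]

    def backward(self, dout):
        xp, (pt, pl), x_shape, (ho, wo) = self._cache
        k, s = self.kernel, self.stride
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros(xp.shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, i : i + s * ho : s, j : j + s * wo : s, :]
                dW[i, j] = (xp[sl] * dout).sum(axis=(0, 1, 2))
                dxp[sl] += dout * W[i, j]
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        _, h, w, _ = x_shape
        return dxp[:, pt : pt + h, pl : pl + w, :]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).copy()


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params = {"W": np.zeros((c_in, c_out)), "b": np.zeros(c_out)}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: identity at inference, rescaled masking in training."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.p
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class SqueezeExcite(Layer):
    """Channel gate: sigmoid(W2 relu(W1 mean(x) + b1) + b2) applied channelwise."""

    def __init__(self, channels: int, ratio: int = 4):
        super().__init__()
        if ratio < 1:
            raise ValueError("SE reduction ratio must be >= 1")
        reduced = max(1, channels // ratio)
        self.channels, self.reduced = channels, reduced
        self.params = {
            "W1": np.zeros((channels, reduced)),
            "b1": np.zeros(reduced),
            "W2": np.zeros((reduced, channels)),
            "b2": np.zeros(channels),
        }

    def forward(self, x, training=False):
        s = x.mean(axis=(1, 2))
        z1 = s @ self.params["W1"] + self.params["b1"]
        h = np.where(z1 > 0, z1, 0.0)
        g = sigmoid(h @ self.params["W2"] + self.params["b2"])
        self._cache = (x, s, z1, h, g)
        return x * g[:, None, None, :]

    def backward(self, dout):
        x, s, z1, h, g = self._cache
        n, hh, ww, c = x.shape
        dx = dout * g[:, None, None, :]
        dg = (dout * x).sum(axis=(1, 2))
        dz2 = dg * g * (1.0 - g)
        self.grads["W2"] = h.T @ dz2
        self.grads["b2"] = dz2.sum(axis=0)
        dh = dz2 @ self.params["W2"].T
        dz1 = np.where(z1 > 0, dh, 0.0)
        self.grads["W1"] = s.T @ dz1
        self.grads["b1"] = dz1.sum(axis=0)
        ds = dz1 @ self.params["W1"].T
        dx += ds[:, None, None, :] / (hh * ww)
        return dx
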