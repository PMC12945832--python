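"""Functional single-image MBConv stage operations.

These operate on one (H, W, C) feature map with explicitly supplied
weights and return the bare affine/gated outputs of each stage (no
activation), which makes them convenient for hand-arithmetic checks.
The batched model path in :mod:`glioscope.nn.model` composes the same
stages with ReLU nonlinearities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .layers import sigmoid

__all__ = [
    "MBConvWeights",
    "expand",
    "depthwise",
    "squeeze_excite",
    "project",
    "residual_add",
]


@dataclass
class MBConvWeights:
    """Flat weight container for one mobile inverted bottleneck block.

    Shapes: ``we`` (C_in, C_e); ``wdw`` (k, k, C_e); ``w1`` (C_e, C_r);
    ``w2`` (C_r, C_e); ``wp`` (C_e, C_out); biases match output channels.
    """

    we: np.ndarray
    be: np.ndarray
    wdw: np.ndarray
    bdw: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    wp: np.ndarray
    bp: np.ndarray


def _check_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("feature map must be (H, W, C)")
    return x


def expand(x: np.ndarray, w: MBConvWeights) -> np.ndarray:
    """1x1 channel expansion: We . x + be."""
    x = _check_map(x)
    if x.shape[-1] != w.we.shape[0]:
        raise ValueError("channel count does not match expansion weights")
    return np.einsum("hwc,ce->hwe", x, w.we) + w.be


def depthwise(x: np.ndarray, w: MBConvWeights, stride: int = 1) -> np.ndarray:
    """Per-channel k x k convolution with same padding: Wdw . x + bdw."""
    x = _check_map(x)
    k = w.wdw.shape[0]
    if k % 2 == 0 or w.wdw.shape[0] != w.wdw.shape[1]:
        raise ValueError("depthwise kernel must be square and odd-sized")
    if x.shape[-1] != w.wdw.shape[2]:
        raise ValueError("channel count does not match depthwise weights")
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    patches = sliding_window_view(xp, (k, k), axis=(0, 1))[::stride, ::stride]
    return np.einsum("hwcij,ijc->hwc", patches, w.wdw) + w.bdw


def squeeze_excite(x: np.ndarray, w: MBConvWeights) -> np.ndarray:
    """Channel gate sigmoid(W2 relu(W1 squeeze(x) + b1) + b2) applied to x.

    The squeeze is a global average pool over the spatial axes.
    """
    x = _check_map(x)
    if x.shape[-1] != w.w1.shape[0]:
        raise ValueError("channel count does not match SE weights")
    s = x.mean(axis=(0, 1))
    h = np.maximum(s @ w.w1 + w.b1, 0.0)
    gate = sigmoid(h @ w.w2 + w.b2)
    return x * gate


def project(x: np.ndarray, w: MBConvWeights) -> np.ndarray:
    """Linear 1x1 projection: Wp . x + bp."""
    x = _check_map(x)
    if x.shape[-1] != w.wp.shape[0]:
        raise ValueError("channel count does not match projection weights")
    return np.einsum("hwe,eo->hwo", x, w.wp) + w.bp


def residual_add(xp: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Elementwise skip connection xp + x; shapes must match exactly."""
    xp = _check_map(xp)
    x = _check_map(x)
    if xp.shape != x.shape:
        raise ValueError(
            f"residual shapes must match, got {xp.shape} and {x.shape}"
        )
    return xp + x
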