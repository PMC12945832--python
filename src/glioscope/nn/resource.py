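"""Deterministic, architecture-only resource accounting.

Model size is the exact trainable-parameter count (reported in millions)
and the latency proxy is the multiply-accumulate count of one forward
pass divided by 1e6.  Both depend only on the configuration, never on
weight values, so they are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ModelConfig

__all__ = ["ResourceCost", "resource_cost"]


@dataclass(frozen=True)
class ResourceCost:
    c_size: float  # parameters, millions
    c_latency: float  # MAC count / 1e6, ms-equivalent units
    n_params: int
    n_macs: int


def _out_hw(h: int, w: int, stride: int) -> tuple[int, int]:
    return -(-h // stride), -(-w // stride)


def resource_cost(config: ModelConfig) -> ResourceCost:
    params = 0
    macs = 0
    h, w = config.input_hw

    # stem: 3x3, stride 1
    c_in, c_out = config.in_channels, config.stem_channels
    params += 9 * c_in * c_out + c_out
    macs += h * w * 9 * c_in * c_out
    c = c_out

    for spec in config.blocks:
        ce = c * spec.expansion
        cr = max(1, ce // spec.se_ratio)
        # expansion 1x1 at input resolution
        params += c * ce + ce
        macs += h * w * c * ce
        # depthwise at output resolution
        h, w = _out_hw(h, w, spec.stride)
        params += spec.kernel**2 * ce + ce
        macs += h * w * spec.kernel**2 * ce
        # squeeze-and-excitation (two dense maps on pooled channels)
        params += ce * cr + cr + cr * ce + ce
        macs += ce * cr + cr * ce
        # projection 1x1
        params += ce * spec.out_channels + spec.out_channels
        macs += h * w * ce * spec.out_channels
        c = spec.out_channels

    # classification head
    params += c * config.n_classes + config.n_classes
    macs += c * config.n_classes

    return ResourceCost(
        c_size=params / 1e6, c_latency=macs / 1e6, n_params=params, n_macs=macs
    )
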