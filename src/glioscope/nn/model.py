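"""Small mobile-inverted-bottleneck classifier.

Block structure: 1x1 expansion (+ReLU), depthwise convolution (+ReLU),
squeeze-and-excitation gate, linear 1x1 projection, and an identity skip
whenever stride is 1 and the channel count is preserved.  No normalization
layers are used, keeping forward passes fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    Conv2D,
    Dense,
    DepthwiseConv2D,
    Dropout,
    GlobalAvgPool,
    Layer,
    ReLU,
    SqueezeExcite,
    softmax,
)

__all__ = ["BlockSpec", "ModelConfig", "MBConvBlock", "MnasLite", "forward"]


@dataclass(frozen=True)
class BlockSpec:
    expansion: int
    kernel: int
    stride: int
    out_channels: int
    se_ratio: int = 4

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.expansion < 1:
            raise ValueError("expansion factor must be >= 1")


def _default_blocks():
    return (
        BlockSpec(expansion=3, kernel=3, stride=2, out_channels=16, se_ratio=4),
        BlockSpec(expansion=3, kernel=3, stride=2, out_channels=24, se_ratio=4),
        BlockSpec(expansion=3, kernel=3, stride=1, out_channels=24, se_ratio=4),
    )


@dataclass(frozen=True)
class ModelConfig:
    """Desk-scale default: 32x32 single-channel input, 3 blocks, 2 classes."""

    input_hw: tuple[int, int] = (32, 32)
    in_channels: int = 1
    stem_channels: int = 8
    blocks: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    n_classes: int = 2
    dropout: float = 0.25

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(self.blocks))


class MBConvBlock(Layer):
    def __init__(self, c_in: int, spec: BlockSpec):
        super().__init__()
        ce = c_in * spec.expansion
        self.spec = spec
        self.c_in, self.c_out = c_in, spec.out_channels
        self.expand = Conv2D(1, c_in, ce)
        self.relu1 = ReLU()
        self.dw = DepthwiseConv2D(spec.kernel, ce, stride=spec.stride)
        self.relu2 = ReLU()
        self.se = SqueezeExcite(ce, spec.se_ratio)
        self.project = Conv2D(1, ce, spec.out_channels)
        self.residual = spec.stride == 1 and c_in == spec.out_channels

    @property
    def sublayers(self):
        return [self.expand, self.dw, self.se, self.project]

    def forward(self, x, training=False):
        y = self.relu1.forward(self.expand.forward(x, training), training)
        y = self.relu2.forward(self.dw.forward(y, training), training)
        y = self.se.forward(y, training)
        y = self.project.forward(y, training)
        if self.residual:
            y = y + x
        return y

    def backward(self, dout):
        dx = self.project.backward(dout)
        dx = self.se.backward(dx)
        dx = self.dw.backward(self.relu2.backward(dx))
        dx = self.expand.backward(self.relu1.backward(dx))
        if self.residual:
            dx = dx + dout
        return dx


class MnasLite:
    """Stem conv -> MBConv stack -> global pool -> dropout -> linear head."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        cfg = self.config
        self.stem = Conv2D(3, cfg.in_channels, cfg.stem_channels)
        self.stem_relu = ReLU()
        self.blocks: list[MBConvBlock] = []
        c = cfg.stem_channels
        for spec in cfg.blocks:
            self.blocks.append(MBConvBlock(c, spec))
            c = spec.out_channels
        self.pool = GlobalAvgPool()
        self.dropout = Dropout(cfg.dropout, seed=seed)
        self.head = Dense(c, cfg.n_classes)
        # provenance of the data this model was trained on (leakage guard)
        self.trained_patient_ids: frozenset = frozenset()

    # --- parameter plumbing -------------------------------------------------
    def param_layers(self) -> list[tuple[str, Layer]]:
        out = [("stem", self.stem)]
        for i, blk in enumerate(self.blocks):
            for name, lyr in zip(("expand", "dw", "se", "project"), blk.sublayers):
                out.append((f"block{i}.{name}", lyr))
        out.append(("head", self.head))
        return out

    def param_items(self):
        for lname, layer in self.param_layers():
            for key in layer.params:
                yield f"{lname}.{key}", layer.params, key

    def n_parameters(self) -> int:
        return sum(p[key].size for _, p, key in self.param_items())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: p[key].copy() for name, p, key in self.param_items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, p, key in self.param_items():
            p[key] = np.array(weights[name], dtype=float)

    # --- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cfg = self.config
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != cfg.input_hw or x.shape[3] != cfg.in_channels:
            raise ValueError(
                f"expected input {cfg.input_hw + (cfg.in_channels,)}, got {x.shape[1:]}"
            )
        y = self.stem_relu.forward(self.stem.forward(x, training), training)
        for blk in self.blocks:
            y = blk.forward(y, training)
        y = self.pool.forward(y, training)
        y = self.dropout.forward(y, training)
        return self.head.forward(y, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dx = self.head.backward(dlogits)
        dx = self.dropout.backward(dx)
        dx = self.pool.backward(dx)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        return self.stem.backward(self.stem_relu.backward(dx))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward_logits(x, training=False), axis=1)


def forward(model: MnasLite, images: np.ndarray) -> np.ndarray:
    """Class probability rows (each summing to 1) for a batch of images."""
    return model.predict_proba(images)


def config_to_yaml(config: ModelConfig) -> str:
    """Serialize a model configuration as a YAML block."""
    import yaml

    payload = {
        "input_hw": list(config.input_hw),
        "in_channels": config.in_channels,
        "stem_channels": config.stem_channels,
        "n_classes": config.n_classes,
        "dropout": config.dropout,
        "blocks": [
            {
                "expansion": b.expansion,
                "kernel": b.kernel,
                "stride": b.stride,
                "out_channels": b.out_channels,
                "se_ratio": b.se_ratio,
            }
            for b in config.blocks
        ],
    }
    return yaml.safe_dump(payload, sort_keys=False)


def config_from_yaml(text: str) -> ModelConfig:
    import yaml

    payload = yaml.safe_load(text)
    return ModelConfig(
        input_hw=tuple(payload["input_hw"]),
        in_channels=payload["in_channels"],
        stem_channels=payload["stem_channels"],
        blocks=tuple(BlockSpec(**b) for b in payload["blocks"]),
        n_classes=payload["n_classes"],
        dropout=payload["dropout"],
    )


def save_checkpoint(model: MnasLite, path) -> None:
    """Write weights as a flat named-array archive plus the config YAML."""
    from pathlib import Path

    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.get_weights())
    path.with_suffix(".yaml").write_text(config_to_yaml(model.config))


def load_checkpoint(path) -> MnasLite:
    from pathlib import Path

    path = Path(path)
    model = MnasLite(config_from_yaml(path.with_suffix(".yaml").read_text()))
    with np.load(path.with_suffix(".npz")) as archive:
        model.set_weights(dict(archive))
    return model
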