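"""SGD-with-momentum training loop.

Classic (non-decoupled) L2 weight decay folded into the gradient,
exponential learning-rate decay applied once per epoch, seeded shuffling,
no early stopping: the loop always runs the configured number of epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.losses import cross_entropy_grad
from .nn.model import MnasLite

__all__ = [
    "TrainConfig",
    "TrainReport",
    "init_weights",
    "sgd_momentum_step",
    "apply_dropout",
    "train_model",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.0016
    batch_size: int = 256
    epochs: int = 60
    weight_decay: float = 0.0003
    momentum: float = 0.92
    dropout: float = 0.25
    init_scheme: str = "xavier_normal"
    lr_decay: float = 0.97
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be positive, epochs nonnegative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if self.init_scheme not in ("xavier_normal", "he_normal"):
            raise ValueError(f"unknown init scheme {self.init_scheme!r}")


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    final_weights: dict | None = None
    config: TrainConfig | None = None


def _fans(name: str, arr: np.ndarray) -> tuple[int, int]:
    if arr.ndim == 4:  # conv (k, k, c_in, c_out)
        k = arr.shape[0] * arr.shape[1]
        return k * arr.shape[2], k * arr.shape[3]
    if arr.ndim == 3:  # depthwise (k, k, c): one input/output channel per filter
        k = arr.shape[0] * arr.shape[1]
        return k, k
    if arr.ndim == 2:  # dense (c_in, c_out)
        return arr.shape[0], arr.shape[1]
    raise ValueError(f"cannot infer fans for {name} with shape {arr.shape}")


def init_std(scheme: str, fan_in: int, fan_out: int) -> float:
    """Normal-init standard deviation for the given fan counts."""
    if scheme == "xavier_normal":
        return float(np.sqrt(2.0 / (fan_in + fan_out)))
    if scheme == "he_normal":
        return float(np.sqrt(2.0 / fan_in))
    raise ValueError(f"unknown init scheme {scheme!r}")


def init_weights(model: MnasLite, scheme: str, seed: int) -> MnasLite:
    """Draw every weight tensor from a zero-mean normal; biases are zeroed."""
    rng = np.random.default_rng(seed)
    for name, params, key in model.param_items():
        if key == "b" or key.startswith("b"):
            params[key] = np.zeros_like(params[key])
        else:
            fan_in, fan_out = _fans(name, params[key])
            std = init_std(scheme, fan_in, fan_out)
            params[key] = rng.normal(0.0, std, size=params[key].shape)
    return model


def sgd_momentum_step(w, grad, velocity, config: TrainConfig, lr: float | None = None):
    """One momentum update: v' = mu*v - lr*(grad + wd*w); w' = w + v'."""
    grad = np.asarray(grad, dtype=float)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(
            f"non-finite gradient encountered (max |g| = {np.abs(grad).max()!r})"
        )
    if lr is None:
        lr = config.learning_rate
    v_new = config.momentum * velocity - lr * (grad + config.weight_decay * w)
    return w + v_new, v_new


def apply_dropout(activations, p: float, seed: int, training_flag: bool):
    """Inverted dropout on an activation array; identity at inference."""
    if not 0.0 <= p < 1.0:
        raise ValueError("dropout probability must lie in [0, 1)")
    if not training_flag or p == 0.0:
        return np.asarray(activations, dtype=float)
    rng = np.random.default_rng(seed)
    keep = rng.random(np.shape(activations)) >= p
    return np.asarray(activations, dtype=float) * keep / (1.0 - p)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):  # final short batch kept
        yield order[start : start + batch_size]


def evaluate_loss_acc(model: MnasLite, x: np.ndarray, y: np.ndarray, batch_size: int = 256):
    losses, correct, n = [], 0, x.shape[0]
    for start in range(0, n, batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        logits = model.forward_logits(xb, training=False)
        loss, _ = cross_entropy_grad(logits, yb)
        losses.append(loss * xb.shape[0])
        correct += int(np.sum(np.argmax(logits, axis=1) == yb))
    return float(np.sum(losses) / n), correct / n


def train_model(model: MnasLite, data: dict, config: TrainConfig) -> TrainReport:
    """Train ``model`` on ``data`` = {"train": (X, y), "val": (X, y)}.

    Optional ``data["train_patient_ids"]`` records provenance on the model
    so later evaluation can detect train/test overlap.
    """
    x_tr, y_tr = data["train"]
    x_va, y_va = data["val"]
    if x_tr.shape[0] == 0:
        raise ValueError("training partition is empty")
    x_tr = np.asarray(x_tr, dtype=float)
    x_va = np.asarray(x_va, dtype=float)
    y_tr = np.asarray(y_tr, dtype=int)
    y_va = np.asarray(y_va, dtype=int)

    init_weights(model, config.init_scheme, config.seed)
    model.dropout.p = config.dropout
    model.dropout.rng = np.random.default_rng(config.seed + 1)
    if "train_patient_ids" in data:
        model.trained_patient_ids = frozenset(data["train_patient_ids"])

    rng = np.random.default_rng(config.seed + 2)
    # bind (name, layer, key) once so the update loop is O(n_params)
    bindings = [
        (f"{lname}.{key}", layer, key)
        for lname, layer in model.param_layers()
        for key in layer.params
    ]
    velocity = {name: np.zeros_like(layer.params[key]) for name, layer, key in bindings}
    report = TrainReport(config=config)

    lr = config.learning_rate
    for _ in range(config.epochs):
        epoch_loss, seen = 0.0, 0
        for idx in _batches(x_tr.shape[0], config.batch_size, rng):
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.forward_logits(xb, training=True)
            loss, dlogits = cross_entropy_grad(logits, yb)
            model.backward(dlogits)
            for name, layer, key in bindings:
                w_new, v_new = sgd_momentum_step(
                    layer.params[key], layer.grads[key], velocity[name], config, lr=lr
                )
                layer.params[key] = w_new
                velocity[name] = v_new
            epoch_loss += loss * xb.shape[0]
            seen += xb.shape[0]
        lr *= config.lr_decay
        val_loss, val_acc = evaluate_loss_acc(model, x_va, y_va)
        report.train_loss.append(epoch_loss / seen)
        report.val_loss.append(val_loss)
        report.val_accuracy.append(val_acc)

    report.final_weights = model.get_weights()
    return report
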