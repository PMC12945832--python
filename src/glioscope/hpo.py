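"""Hyperparameter search over the training-configuration space.

The ten-dimensional search space (learning rate, weight decay, momentum,
dropout, two resource trade-off coefficients, batch size, epoch count,
init scheme, augmentation policy) is encoded into the unit cube so the
single-candidate optimizers can drive it.  Each candidate is scored by
training the desk-scale model and combining validation cross-entropy
with the deterministic resource penalties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .asco import run_asco
from .errors import EvaluationError
from .nn.model import MnasLite, ModelConfig
from .nn.resource import resource_cost
from .nn.losses import loss_total
from .preprocess import AugmentPolicy
from .sco import ScoConfig, SearchSpace, run_sco
from .trainer import TrainConfig, train_model

__all__ = [
    "HyperParams",
    "HyperSpace",
    "EvalConfig",
    "HpoResult",
    "default_hyperparams",
    "objective_eval",
    "run_hpo",
    "ablation_study",
]

BATCH_CHOICES = (64, 128, 192, 256)
EPOCH_CHOICES = tuple(range(40, 61))
INIT_CHOICES = ("xavier_normal", "he_normal")
AUG_CHOICES = ("crop+flip_h", "crop+flip_v", "rotate+jitter")

AUG_POLICIES = {
    "crop+flip_h": ("crop", "flip_h"),
    "crop+flip_v": ("crop", "flip_v"),
    "rotate+jitter": ("rotate", "color_jitter"),
}


@dataclass(frozen=True)
class HyperParams:
    learning_rate: float
    weight_decay: float
    momentum: float
    dropout: float
    lam1: float
    lam2: float
    batch_size: int
    epochs: int
    init_scheme: str
    augment_policy: str


def default_hyperparams() -> HyperParams:
    """Reference fixed configuration used as the search baseline."""
    return HyperParams(
        learning_rate=0.0016,
        weight_decay=0.0003,
        momentum=0.92,
        dropout=0.25,
        lam1=8.7e-3,
        lam2=4.2e-4,
        batch_size=256,
        epochs=60,
        init_scheme="xavier_normal",
        augment_policy="rotate+jitter",
    )


class HyperSpace:
    """Affine/log encoding of the hyperparameter domain into [0, 1]^10.

    Continuous dims: learning rate and weight decay on log scale, the
    rest linear.  Categorical dims use equal-width bins of the unit
    interval, decoded with ties toward the lower bin; grid values encode
    to bin centers so decode(encode(hp)) round-trips exactly.
    """

    dim = 10

    _log_dims = {0: (1e-4, 1e-2), 1: (1e-5, 1e-3)}
    _lin_dims = {2: (0.85, 0.99), 3: (0.1, 0.4), 4: (1e-4, 1e-2), 5: (1e-5, 1e-3)}
    _cat_dims = {6: BATCH_CHOICES, 7: EPOCH_CHOICES, 8: INIT_CHOICES, 9: AUG_CHOICES}

    def encode(self, hp: HyperParams) -> np.ndarray:
        vals = (
            hp.learning_rate,
            hp.weight_decay,
            hp.momentum,
            hp.dropout,
            hp.lam1,
            hp.lam2,
            hp.batch_size,
            hp.epochs,
            hp.init_scheme,
            hp.augment_policy,
        )
        u = np.empty(self.dim)
        for i, v in enumerate(vals):
            if i in self._log_dims:
                lo, hi = self._log_dims[i]
                if not lo <= v <= hi:
                    raise ValueError(f"dim {i} value {v} outside [{lo}, {hi}]")
                u[i] = (math.log10(v) - math.log10(lo)) / (math.log10(hi) - math.log10(lo))
            elif i in self._lin_dims:
                lo, hi = self._lin_dims[i]
                if not lo <= v <= hi:
                    raise ValueError(f"dim {i} value {v} outside [{lo}, {hi}]")
                u[i] = (v - lo) / (hi - lo)
            else:
                choices = self._cat_dims[i]
                if v not in choices:
                    raise ValueError(f"dim {i} value {v!r} not in {choices}")
                u[i] = (choices.index(v) + 0.5) / len(choices)
        return u

    def decode(self, u) -> HyperParams:
        u = np.asarray(u, dtype=float)
        if u.shape != (self.dim,):
            raise ValueError(f"unit vector must have length {self.dim}")
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("unit vector entries must lie in [0, 1]")
        out = []
        for i, ui in enumerate(u):
            if i in self._log_dims:
                lo, hi = self._log_dims[i]
                out.append(10 ** (math.log10(lo) + ui * (math.log10(hi) - math.log10(lo))))
            elif i in self._lin_dims:
                lo, hi = self._lin_dims[i]
                out.append(lo + ui * (hi - lo))
            else:
                choices = self._cat_dims[i]
                out.append(choices[min(int(ui * len(choices)), len(choices) - 1)])
        return HyperParams(
            learning_rate=out[0],
            weight_decay=out[1],
            momentum=out[2],
            dropout=out[3],
            lam1=out[4],
            lam2=out[5],
            batch_size=out[6],
            epochs=out[7],
            init_scheme=out[8],
            augment_policy=out[9],
        )


@dataclass(frozen=True)
class EvalConfig:
    """Desk-scale controls for candidate evaluation."""

    model_config: ModelConfig = field(default_factory=ModelConfig)
    max_epochs: int | None = None  # cap decoded epoch counts (desk scale)
    seed: int = 0
    augment: bool = False  # add one augmented copy of the training set


def _augmented_train(x_tr, y_tr, policy_name: str, seed: int):
    from .preprocess import augment

    ops = AUG_POLICIES[policy_name]
    policy = AugmentPolicy(ops=ops, seed=seed)
    rng = np.random.default_rng(seed)
    aug = np.stack([augment(im, lab, policy, rng)[0] for im, lab in zip(x_tr, y_tr)])
    return np.concatenate([x_tr, aug]), np.concatenate([y_tr, y_tr])


def objective_eval(u, data, eval_config: EvalConfig) -> float:
    """Train the desk-scale model with the decoded candidate and score it.

    Score = final-epoch validation cross-entropy + lam1 * latency proxy
    + lam2 * parameter count (millions).  Raises
    :class:`EvaluationError` on non-finite results; the optimizer-facing
    wrapper converts that into an adaptive penalty.
    """
    space = HyperSpace()
    hp = space.decode(u)
    epochs = hp.epochs if eval_config.max_epochs is None else min(hp.epochs, eval_config.max_epochs)
    cfg = replace(eval_config.model_config, dropout=hp.dropout)
    model = MnasLite(cfg, seed=eval_config.seed)
    x_tr, y_tr = data["train"]
    if eval_config.augment:
        x_tr, y_tr = _augmented_train(x_tr, y_tr, hp.augment_policy, eval_config.seed)
    tc = TrainConfig(
        learning_rate=hp.learning_rate,
        batch_size=hp.batch_size,
        epochs=epochs,
        weight_decay=hp.weight_decay,
        momentum=hp.momentum,
        dropout=hp.dropout,
        init_scheme=hp.init_scheme,
        seed=eval_config.seed,
    )
    report = train_model(model, {"train": (x_tr, y_tr), "val": data["val"]}, tc)
    l_ce = report.val_loss[-1] if report.val_loss else _untrained_val_loss(model, data)
    cost = resource_cost(cfg)
    val = loss_total(l_ce, cost, hp.lam1, hp.lam2)
    if not np.isfinite(val):
        raise EvaluationError(u, val)
    return val


def _untrained_val_loss(model, data):
    from .trainer import evaluate_loss_acc

    x_va, y_va = data["val"]
    return evaluate_loss_acc(model, np.asarray(x_va, dtype=float), np.asarray(y_va))[0]


class _TraceObjective:
    """Records every evaluation and converts failures into adaptive penalties."""

    def __init__(self, fn):
        self.fn = fn
        self.trace: list[tuple[np.ndarray, float]] = []
        self.worst_finite = None

    def __call__(self, u):
        try:
            val = float(self.fn(u))
            if not np.isfinite(val):
                raise EvaluationError(u, val)
            self.worst_finite = val if self.worst_finite is None else max(self.worst_finite, val)
        except (EvaluationError, FloatingPointError):
            val = 10.0 * max(self.worst_finite or 0.0, 1e3)
        self.trace.append((np.array(u), val))
        return val


@dataclass
class HpoResult:
    best_hp: HyperParams
    best_u: np.ndarray
    best_f: float
    traces: list = field(repr=False, default_factory=list)
    seeds: tuple = ()
    default_f: float | None = None


def run_hpo(
    algo: str,
    budget: int,
    data,
    seeds=(0,),
    eval_config: EvalConfig | None = None,
    objective=None,
    include_default: bool = True,
) -> HpoResult:
    """Run SCO or ASCO over the hyperparameter space.

    ``objective`` may replace the training-based evaluation with any
    callable on the unit cube (used for surrogate validation).  When
    ``include_default`` is set the fixed reference configuration is also
    evaluated and the returned best can never be worse than it.
    """
    if algo not in ("sco", "asco"):
        raise ValueError("algo must be 'sco' or 'asco'")
    if budget < 2:
        raise ValueError("budget must be at least 2")
    eval_config = eval_config or EvalConfig()
    hs = HyperSpace()
    space = SearchSpace(lb=np.zeros(hs.dim), ub=np.ones(hs.dim))
    base = objective if objective is not None else (
        lambda u: objective_eval(u, data, eval_config)
    )

    best_u, best_f, traces = None, np.inf, []
    for seed in seeds:
        wrapped = _TraceObjective(base)
        config = ScoConfig(T=budget, seed=seed)
        runner = run_asco if algo == "asco" else run_sco
        res = runner(wrapped, space, config)
        traces.append(wrapped.trace)
        if res.f_gbest < best_f:
            best_f, best_u = res.f_gbest, res.gbest

    default_f = None
    if include_default:
        u_def = hs.encode(default_hyperparams())
        wrapped = _TraceObjective(base)
        default_f = wrapped(u_def)
        traces.append(wrapped.trace)
        if default_f < best_f:
            best_f, best_u = default_f, u_def

    return HpoResult(
        best_hp=hs.decode(best_u),
        best_u=np.asarray(best_u),
        best_f=float(best_f),
        traces=traces,
        seeds=tuple(seeds),
        default_f=default_f,
    )


def ablation_study(data, configs: dict, eval_config: EvalConfig | None = None):
    """Train and test each named hyperparameter configuration identically.

    ``data`` needs train/val/test partitions (and optionally
    ``test_patient_ids``/``train_patient_ids`` for the leakage guard).
    Returns ``{name: (MetricReport, ConfusionCounts)}``.
    """
    from .evaluation import evaluate

    eval_config = eval_config or EvalConfig()
    out = {}
    for name, hp in configs.items():
        epochs = hp.epochs if eval_config.max_epochs is None else min(hp.epochs, eval_config.max_epochs)
        cfg = replace(eval_config.model_config, dropout=hp.dropout)
        model = MnasLite(cfg, seed=eval_config.seed)
        tc = TrainConfig(
            learning_rate=hp.learning_rate,
            batch_size=hp.batch_size,
            epochs=epochs,
            weight_decay=hp.weight_decay,
            momentum=hp.momentum,
            dropout=hp.dropout,
            init_scheme=hp.init_scheme,
            seed=eval_config.seed,
        )
        train_data = {"train": data["train"], "val": data["val"]}
        if "train_patient_ids" in data:
            train_data["train_patient_ids"] = data["train_patient_ids"]
        train_model(model, train_data, tc)
        x_te, y_te = data["test"]
        out[name] = evaluate(model, x_te, y_te, data.get("test_patient_ids"))
    return out
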