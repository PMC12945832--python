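"""End-to-end pipeline: contrast enhancement -> training -> evaluation.

Split first, then per-image CLAHE, augmentation on the training partition
only, normalization with training-partition statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import evaluate, kfold, stratified_split
from .nn.model import MnasLite, ModelConfig
from .preprocess import (
    AugmentPolicy,
    ClaheParams,
    augment,
    clahe,
    compute_norm_stats,
    normalize,
    resize_batch,
)
from .trainer import TrainConfig, train_model

__all__ = ["PipelineConfig", "CvResult", "prepare_images", "run_holdout", "run_cv"]


@dataclass(frozen=True)
class PipelineConfig:
    clahe_params: ClaheParams = field(default_factory=ClaheParams)
    model_config: ModelConfig = field(default_factory=ModelConfig)
    # desk-scale training defaults: small batches and few epochs converge
    # quickly on the phantom task
    train_config: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=0.005,
            batch_size=16,
            epochs=18,
            weight_decay=0.0003,
            momentum=0.95,
            dropout=0.0,
            init_scheme="he_normal",
            lr_decay=0.9,
            seed=0,
        )
    )
    augment_policy: AugmentPolicy | None = None
    val_fraction: float = 0.12
    seed: int = 0


def prepare_images(images: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """CLAHE each slice then resize to the model input size (float in [0, 1])."""
    out = np.stack([clahe(im, config.clahe_params) for im in np.asarray(images, dtype=float)])
    return resize_batch(out, config.model_config.input_hw)


def _train_eval(x, y, pids, train_idx, val_idx, test_idx, config: PipelineConfig, fold_seed: int):
    x_tr, y_tr = x[train_idx], y[train_idx]
    if config.augment_policy is not None:
        rng = np.random.default_rng(fold_seed)
        aug = np.stack(
            [augment(im, lab, config.augment_policy, rng)[0] for im, lab in zip(x_tr, y_tr)]
        )
        x_tr = np.concatenate([x_tr, aug])
        y_tr = np.concatenate([y_tr, y_tr])
    stats = compute_norm_stats(x_tr, source="train")
    x_tr_n = normalize(x_tr, stats)
    x_va_n = normalize(x[val_idx], stats)
    x_te_n = normalize(x[test_idx], stats)

    model = MnasLite(config.model_config, seed=fold_seed)
    tc = TrainConfig(**{**config.train_config.__dict__, "seed": fold_seed})
    data = {
        "train": (x_tr_n, y_tr),
        "val": (x_va_n, y[val_idx]),
        "train_patient_ids": [pids[i] for i in np.concatenate([train_idx, val_idx])],
    }
    report = train_model(model, data, tc)
    mrep, counts = evaluate(model, x_te_n, y[test_idx], [pids[i] for i in test_idx])
    return model, report, mrep, counts


def run_holdout(images, labels, patient_ids, config: PipelineConfig | None = None):
    """80/10/10 stratified hold-out run; returns (MetricReport, ConfusionCounts, report)."""
    config = config or PipelineConfig()
    x = prepare_images(images, config)
    y = np.asarray(labels, dtype=int)
    pids = list(patient_ids)
    split = stratified_split(pids, y, seed=config.seed)
    part = np.array([split.assignment[p] for p in pids])
    idx = {name: np.flatnonzero(part == name) for name in ("train", "val", "test")}
    _, report, mrep, counts = _train_eval(
        x, y, pids, idx["train"], idx["val"], idx["test"], config, config.seed
    )
    return mrep, counts, report


@dataclass
class CvResult:
    fold_reports: list
    fold_counts: list

    def mean_std(self, metric: str):
        vals = np.array([getattr(r, metric) for r in self.fold_reports], dtype=float)
        return float(np.nanmean(vals)), float(np.nanstd(vals))


def run_cv(images, labels, patient_ids, k: int = 10, config: PipelineConfig | None = None) -> CvResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Each fold serves once as the test partition; a small validation share
    is carved out of the remaining patients for the training report.
    """
    config = config or PipelineConfig()
    x = prepare_images(images, config)
    y = np.asarray(labels, dtype=int)
    pids = list(patient_ids)
    folds = kfold(pids, y, k=k, seed=config.seed)
    fold_of = np.array([folds.assignment[p] for p in pids])

    reports, all_counts = [], []
    for fold in range(k):
        test_idx = np.flatnonzero(fold_of == fold)
        rest = np.flatnonzero(fold_of != fold)
        rng = np.random.default_rng(config.seed + fold)
        rest = rng.permutation(rest)
        n_val = max(1, int(round(config.val_fraction * rest.size)))
        val_idx, train_idx = rest[:n_val], rest[n_val:]
        _, _, mrep, counts = _train_eval(
            x, y, pids, train_idx, val_idx, test_idx, config, config.seed + fold
        )
        reports.append(mrep)
        all_counts.append(counts)
    return CvResult(fold_reports=reports, fold_counts=all_counts)
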