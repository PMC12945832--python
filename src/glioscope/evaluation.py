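"""Confusion-matrix metrics, patient-level stratified splitting, and
k-fold cross-validation.

All partitions are assigned at the patient level (one image per patient)
and stratified by label.  Splits are deterministic per seed, disjoint,
and exhaustive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GlioscopeError, LeakageError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "SplitAssignment",
    "metrics",
    "stratified_split",
    "kfold",
    "evaluate",
]


class UndefinedMetricError(GlioscopeError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    sensitivity: float
    precision: float
    specificity: float
    f1: float
    accuracy: float
    mcc: float
    undefined: tuple[str, ...] = ()  # metrics whose denominator was zero


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Six standard binary-classification statistics.

    MCC uses the standard numerator TP*TN - FP*FN.  Metrics with a zero
    denominator are returned as NaN and listed in ``undefined`` rather
    than silently coerced to 0.
    """
    if counts.total == 0:
        raise UndefinedMetricError("cannot compute metrics from empty counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: list[str] = []
    sens = _ratio(tp, tp + fn, "sensitivity", undefined)
    prec = _ratio(tp, tp + fp, "precision", undefined)
    spec = _ratio(tn, tn + fp, "specificity", undefined)
    if math.isnan(sens) or math.isnan(prec) or prec + sens == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    acc = (tp + tn) / counts.total
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricReport(
        sensitivity=sens,
        precision=prec,
        specificity=spec,
        f1=f1,
        accuracy=acc,
        mcc=mcc,
        undefined=tuple(undefined),
    )


@dataclass
class SplitAssignment:
    """patient_id -> partition name ('train'/'val'/'test') or fold index."""

    assignment: dict = field(default_factory=dict)

    def ids_for(self, part) -> list:
        return [pid for pid, p in self.assignment.items() if p == part]

    def sizes(self) -> dict:
        out: dict = {}
        for part in self.assignment.values():
            out[part] = out.get(part, 0) + 1
        return out


def _split_sizes(n: int, fractions) -> tuple[int, int, int]:
    f_tr, f_va, f_te = fractions
    n_train = math.floor(f_tr * n + 1e-9)
    rem = n - n_train
    n_val = math.ceil(rem * f_va / (f_va + f_te) - 1e-9)
    return n_train, n_val, rem - n_val


def _largest_remainder(totals: np.ndarray, target: int) -> np.ndarray:
    """Integer allocation proportional to ``totals`` summing to ``target``."""
    if totals.sum() == 0:
        return np.zeros_like(totals)
    ideal = totals * target / totals.sum()
    base = np.floor(ideal).astype(int)
    short = target - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:short]] += 1
    return base


def stratified_split(patient_ids, labels, fractions=(0.8, 0.1, 0.1), seed=0) -> SplitAssignment:
    """Patient-level stratified train/val/test split.

    Global sizes follow floor(f_train*n) for training; the remainder is
    divided with the validation share rounded up (80/10/10 on 533 records
    gives 426/54/53).  Records are allocated per label stratum by largest
    remainder so the global sizes hold exactly while strata stay balanced
    within one record.
    """
    patient_ids = list(patient_ids)
    labels = np.asarray(labels)
    if len(patient_ids) != len(labels):
        raise ValueError("patient_ids and labels must have equal length")
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("patient_ids must be unique (one image per patient)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(patient_ids)
    n_tr, n_va, n_te = _split_sizes(n, fractions)

    uniq, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        warnings.warn(
            "a label stratum has fewer than 3 patients; falling back to a "
            "global (unstratified) split",
            stacklevel=2,
        )
        uniq, counts = np.array([0]), np.array([n])
        strata = {0: list(range(n))}
    else:
        strata = {lab: list(np.flatnonzero(labels == lab)) for lab in uniq}
        counts = np.array([len(strata[lab]) for lab in uniq])

    tr_alloc = _largest_remainder(counts.astype(float), n_tr)
    va_alloc = _largest_remainder((counts - tr_alloc).astype(float), n_va)
    te_alloc = counts - tr_alloc - va_alloc
    if te_alloc.min() < 0:  # rare corner: rebalance from validation
        for i in np.flatnonzero(te_alloc < 0):
            va_alloc[i] += te_alloc[i]
            te_alloc[i] = 0

    rng = np.random.default_rng(seed)
    assignment = {}
    for lab, a_tr, a_va in zip(uniq, tr_alloc, va_alloc):
        idx = np.array(strata[lab])
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            part = "train" if k < a_tr else ("val" if k < a_tr + a_va else "test")
            assignment[patient_ids[i]] = part
    return SplitAssignment(assignment=assignment)


def kfold(patient_ids, labels, k=10, seed=0) -> SplitAssignment:
    """Stratified k-fold assignment: patient_id -> fold index in 0..k-1.

    Within each label stratum patients are shuffled and dealt round-robin,
    so fold sizes differ by at most one per stratum (and overall the folds
    partition the cohort).
    """
    patient_ids = list(patient_ids)
    labels = np.asarray(labels)
    if k > len(patient_ids):
        raise ValueError("k must not exceed the number of patients")
    uniq, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class must have at least k patients")
    rng = np.random.default_rng(seed)
    assignment = {}
    offset = 0
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            assignment[patient_ids[i]] = (j + offset) % k
        offset += len(idx)  # stagger so small strata spread across folds
    return SplitAssignment(assignment=assignment)


def evaluate(model, images, labels, patient_ids=None):
    """Argmax evaluation of a trained model on a held-out partition.

    If ``patient_ids`` are supplied and the model records the patients it
    was trained on, any overlap raises :class:`LeakageError`.
    Returns ``(MetricReport, ConfusionCounts)``; class 1 is "positive".
    """
    if patient_ids is not None:
        trained = getattr(model, "trained_patient_ids", frozenset())
        overlap = set(patient_ids) & set(trained)
        if overlap:
            raise LeakageError(
                f"evaluation partition overlaps training patients: "
                f"{sorted(overlap)[:5]}{'...' if len(overlap) > 5 else ''}"
            )
    labels = np.asarray(labels, dtype=int)
    preds = model.predict(np.asarray(images, dtype=float))
    tp = int(np.sum((preds == 1) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return metrics(counts), counts
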