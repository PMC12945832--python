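import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioscope.errors import LeakageError
from glioscope.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    evaluate,
    kfold,
    metrics,
    stratified_split,
)


def _brute_force_metrics(tp, tn, fp, fn):
    """Independent arithmetic oracle (plain Python, no shared code path)."""
    sens = tp / (tp + fn) if tp + fn else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = (
        2 * prec * sens / (prec + sens)
        if not (math.isnan(prec) or math.isnan(sens)) and prec + sens > 0
        else float("nan")
    )
    acc = (tp + tn) / (tp + tn + fp + fn)
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else float("nan")
    return sens, prec, spec, f1, acc, mcc


class TestMetrics:
    def test_perfect(self):
        rep = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (rep.sensitivity, rep.precision, rep.specificity, rep.f1, rep.accuracy, rep.mcc) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0
        )

    def test_inverted(self):
        rep = metrics(ConfusionCounts(tp=0, tn=0, fp=10, fn=10))
        assert rep.accuracy == 0.0
        assert rep.mcc == -1.0

    def test_chance(self):
        rep = metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert rep.accuracy == 0.5
        assert rep.mcc == 0.0

    def test_brute_force_oracle_100_random(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 200, size=4))
            if tp + tn + fp + fn == 0:
                continue
            rep = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            expected = _brute_force_metrics(tp, tn, fp, fn)
            got = (rep.sensitivity, rep.precision, rep.specificity, rep.f1, rep.accuracy, rep.mcc)
            for g, e in zip(got, expected):
                if math.isnan(e):
                    assert math.isnan(g)
                else:
                    assert abs(g - e) <= 1e-12

    def test_f1_internally_consistent(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 100, size=4))
            rep = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity)
            )

    def test_mcc_symmetry_under_swap(self):
        a = metrics(ConfusionCounts(tp=30, tn=20, fp=5, fn=8)).mcc
        b = metrics(ConfusionCounts(tp=20, tn=30, fp=8, fn=5)).mcc
        assert a == pytest.approx(b)

    def test_zero_denominator_flagged(self):
        rep = metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert math.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined

    def test_empty_counts_error(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


def _cohort(n, seed=0, balance=0.5):
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(n)]
    labels = (rng.random(n) >= balance).astype(int)
    # ensure both classes present in reasonable number
    labels[: n // 3] = 0
    labels[n // 3 : 2 * n // 3] = 1
    return ids, labels


class TestStratifiedSplit:
    def test_cohort_533_gives_paper_sizes(self):
        ids, labels = _cohort(533)
        split = stratified_split(ids, labels, seed=3)
        sizes = split.sizes()
        assert (sizes["train"], sizes["val"], sizes["test"]) == (426, 54, 53)

    def test_n100_balanced(self):
        ids, labels = _cohort(100)
        sizes = stratified_split(ids, labels, seed=0).sizes()
        assert (sizes["train"], sizes["val"], sizes["test"]) == (80, 10, 10)

    def test_n10(self):
        ids = [f"p{i}" for i in range(10)]
        labels = [0] * 5 + [1] * 5
        sizes = stratified_split(ids, labels, seed=0).sizes()
        assert (sizes["train"], sizes["val"], sizes["test"]) == (8, 1, 1)

    def test_stratification_balance(self):
        ids, labels = _cohort(200)
        split = stratified_split(ids, labels, seed=1)
        labels = np.asarray(labels)
        by_id = dict(zip(ids, labels))
        for part in ("train", "val", "test"):
            part_labels = np.array([by_id[p] for p in split.ids_for(part)])
            frac = part_labels.mean()
            assert abs(frac - labels.mean()) < 0.08

    def test_deterministic(self):
        ids, labels = _cohort(97)
        a = stratified_split(ids, labels, seed=5).assignment
        b = stratified_split(ids, labels, seed=5).assignment
        assert a == b

    def test_duplicate_patient_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(["a", "a", "b"], [0, 1, 0])

    def test_tiny_class_warns_and_falls_back(self):
        ids = [f"p{i}" for i in range(20)]
        labels = [0] * 18 + [1] * 2
        with pytest.warns(UserWarning):
            split = stratified_split(ids, labels, seed=0)
        sizes = split.sizes()
        assert sizes["train"] + sizes["val"] + sizes["test"] == 20

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(12, 400), seed=st.integers(0, 1000))
    def test_partition_property(self, n, seed):
        ids, labels = _cohort(n, seed=seed)
        split = stratified_split(ids, labels, seed=seed)
        assert set(split.assignment) == set(ids)
        sizes = split.sizes()
        assert sum(sizes.values()) == n
        assert sizes["train"] == int(0.8 * n)


class TestKfold:
    def test_equal_folds_n100(self):
        ids, labels = _cohort(100)
        assignment = kfold(ids, labels, k=10, seed=0).assignment
        sizes = np.bincount(list(assignment.values()))
        assert np.all(sizes == 10)

    def test_each_patient_exactly_one_fold(self):
        ids, labels = _cohort(83)
        assignment = kfold(ids, labels, k=10, seed=2).assignment
        assert set(assignment) == set(ids)

    def test_533_fold_sizes(self):
        ids, labels = _cohort(533)
        assignment = kfold(ids, labels, k=10, seed=0).assignment
        sizes = np.bincount(list(assignment.values()), minlength=10)
        assert set(sizes.tolist()) <= {53, 54}
        assert sizes.sum() == 533

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            kfold(["a", "b"], [0, 1], k=5)

    def test_small_class_rejected(self):
        ids = [f"p{i}" for i in range(30)]
        labels = [0] * 27 + [1] * 3
        with pytest.raises(ValueError):
            kfold(ids, labels, k=10)

    def test_deterministic(self):
        ids, labels = _cohort(60)
        assert kfold(ids, labels, k=5, seed=9).assignment == kfold(ids, labels, k=5, seed=9).assignment

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 500))
    def test_stratified_within_one(self, seed):
        ids, labels = _cohort(120, seed=seed)
        assignment = kfold(ids, labels, k=6, seed=seed).assignment
        labels = np.asarray(labels)
        by_id = dict(zip(ids, labels))
        for lab in (0, 1):
            per_fold = np.bincount(
                [assignment[p] for p in ids if by_id[p] == lab], minlength=6
            )
            assert per_fold.max() - per_fold.min() <= 1


class _ConstantModel:
    trained_patient_ids = frozenset()

    def __init__(self, cls):
        self.cls = cls

    def predict(self, x):
        return np.full(len(x), self.cls, dtype=int)


class _OracleModel:
    trained_patient_ids = frozenset()

    def __init__(self, labels):
        self.labels = np.asarray(labels, dtype=int)

    def predict(self, x):
        return self.labels


class TestEvaluate:
    def test_majority_model_on_balanced_set(self):
        x = np.zeros((20, 4, 4))
        y = np.array([0, 1] * 10)
        rep, counts = evaluate(_ConstantModel(1), x, y)
        assert rep.accuracy == 0.5

    def test_oracle_model_all_ones(self):
        y = np.array([0, 1, 1, 0, 1, 0])
        rep, _ = evaluate(_OracleModel(y), np.zeros((6, 2, 2)), y)
        assert rep.accuracy == 1.0 and rep.mcc == 1.0

    def test_leakage_guard(self):
        model = _OracleModel([0, 1])
        model.trained_patient_ids = frozenset({"p1", "p2"})
        with pytest.raises(LeakageError):
            evaluate(model, np.zeros((2, 2, 2)), [0, 1], patient_ids=["p2", "p9"])

    def test_counts_sum(self):
        y = np.array([0, 1, 1, 0])
        _, counts = evaluate(_ConstantModel(0), np.zeros((4, 2, 2)), y)
        assert counts.total == 4
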