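"""Classification and resource-aware loss terms."""

from __future__ import annotations

import numpy as np

from .resource import ResourceCost

__all__ = ["loss_acc", "loss_eff", "loss_total", "cross_entropy_grad"]

_EPS = 1e-12


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim == 2:
        return labels.astype(float)
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels.astype(int)] = 1.0
    return out


def loss_acc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true classes.

    ``labels`` may be integer class indices or one-hot rows.  True-class
    probabilities are clamped at 1e-12 before the log.
    """
    probs = np.asarray(probs, dtype=float)
    y = _one_hot(labels, probs.shape[1])
    p_true = np.clip((probs * y).sum(axis=1), _EPS, None)
    return float(-np.mean(np.log(p_true)))


def _check_lams(lam1: float, lam2: float) -> None:
    if lam1 < 0 or lam2 < 0:
        raise ValueError("resource trade-off coefficients must be nonnegative")


def loss_eff(cost: ResourceCost, lam1: float, lam2: float) -> float:
    """Resource penalty pairing lam1 with model size and lam2 with latency."""
    _check_lams(lam1, lam2)
    return float(lam1 * cost.c_size + lam2 * cost.c_latency)


def loss_total(l_ce: float, cost: ResourceCost, lam1: float, lam2: float) -> float:
    """Composite objective l_ce + lam1*latency + lam2*size.

    This is the pairing used by the search pipeline (lam1 scales the
    latency proxy, lam2 the parameter count in millions); see
    :func:`loss_eff` for the alternative ordering.
    """
    _check_lams(lam1, lam2)
    return float(l_ce + lam1 * cost.c_latency + lam2 * cost.c_size)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """(loss, dlogits) for softmax cross-entropy, mean over the batch."""
    logits = np.asarray(logits, dtype=float)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    y = _one_hot(labels, logits.shape[1])
    loss = loss_acc(probs, y)
    return loss, (probs - y) / logits.shape[0]
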