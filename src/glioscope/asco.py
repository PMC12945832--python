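"""Opposition-based initialization and a Chebyshev iterate stream on top
of the single-candidate optimizer.

Two changes relative to :func:`glioscope.sco.run_sco`:

* initialization evaluates both a drawn point and its bound-reflected
  opposite and keeps the better of the pair (two evaluations);
* the uniform draws used for initialization come from a Chebyshev map
  ``r <- cos(beta * arccos(r))`` rescaled to [0, 1].

With the configured ``beta = 0.8`` the Chebyshev map is contractive (its
iterates collapse onto the fixed point r = 1), so the stream re-seeds
itself from the pseudo-random generator whenever two successive iterates
are numerically identical; without this guard the "chaotic" source
degenerates to a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ChaosStateError, EvaluationError
from .sco import (
    CandidateState,
    OptimizationResult,
    ScoConfig,
    SearchSpace,
    _evaluate,
    _sco_loop,
    init_candidate,
)

__all__ = [
    "ChaosStream",
    "chebyshev_next",
    "chaotic_uniform",
    "opposite_point",
    "obl_initialize",
    "run_asco",
]

_COLLAPSE_TOL = 1e-12


def _seed_to_unit_open(seed: int) -> float:
    """Fixed affine hash of an integer seed into the open interval (-1, 1)."""
    h = (int(seed) * 2654435761 + 1013904223) % (2**32)
    return -1.0 + 2.0 * (h + 0.5) / 2**32


class ChaosStream:
    """Chebyshev iterate source with collapse-guarded re-seeding."""

    def __init__(self, seed: int = 0, beta_cheb: float = 0.8, seed_value: float | None = None):
        self.beta_cheb = float(beta_cheb)
        self._rng = np.random.default_rng(seed)
        if seed_value is None:
            seed_value = _seed_to_unit_open(seed)
        if not -1.0 < seed_value < 1.0:
            raise ValueError("seed_value must lie in the open interval (-1, 1)")
        self.r = float(seed_value)

    def _reseed(self) -> float:
        # uniform(-1, 1) never returns the endpoint 1, avoiding the fixed point
        return float(self._rng.uniform(-1.0, 1.0))


def chebyshev_next(stream: ChaosStream) -> float:
    """Advance the stream by one Chebyshev step and return the new iterate."""
    r = stream.r
    if abs(r) > 1.0:
        raise ChaosStateError(f"chaos state {r} outside [-1, 1]")
    new = float(np.cos(stream.beta_cheb * np.arccos(r)))
    if abs(new - r) < _COLLAPSE_TOL:
        stream.r = stream._reseed()
    else:
        stream.r = new
    return new


def chaotic_uniform(stream: ChaosStream) -> float:
    """Chebyshev iterate affinely rescaled from [-1, 1] to [0, 1]."""
    return (chebyshev_next(stream) + 1.0) / 2.0


def opposite_point(x: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Bound-reflected opposite: lb + ub - x componentwise."""
    x = np.asarray(x, dtype=float)
    if x.shape != (space.dim,):
        raise ValueError(f"x must have length {space.dim}")
    if not space.contains(x):
        raise ValueError("x must lie within the search-space bounds")
    return space.lb + space.ub - x


def obl_initialize(objective, space: SearchSpace, stream: ChaosStream) -> CandidateState:
    """Draw a chaotic initial point, evaluate it and its opposite, keep the better.

    Consumes two objective evaluations.  On a tie the original draw is kept.
    """
    r4 = np.array([chaotic_uniform(stream) for _ in range(space.dim)])
    x = init_candidate(space, r4)
    x_opp = opposite_point(x, space)
    f_x = _evaluate(objective, x)
    f_opp = _evaluate(objective, x_opp)
    if f_opp < f_x:
        return CandidateState(x=x_opp, gbest=x_opp.copy(), f_gbest=f_opp, t=2)
    return CandidateState(x=x, gbest=x.copy(), f_gbest=f_x, t=2)


def run_asco(
    objective,
    space: SearchSpace,
    config: ScoConfig,
    *,
    beta_cheb: float = 0.8,
    chaos_all_draws: bool = False,
) -> OptimizationResult:
    """Single-candidate search with opposition-based chaotic initialization.

    Identical loop contracts to :func:`glioscope.sco.run_sco` (monotone
    incumbent history, in-bounds iterates, seed-reproducible).  The chaotic
    stream replaces only the initialization draws unless
    ``chaos_all_draws`` extends it to the in-loop direction draws.
    """
    if config.T < 2:
        raise ValueError("run_asco needs T >= 2 (initialization costs 2 evaluations)")
    rng = np.random.default_rng(config.seed)
    stream = ChaosStream(seed=config.seed, beta_cheb=beta_cheb)
    state = obl_initialize(objective, space, stream)
    history = [state.f_gbest, state.f_gbest]
    draw = None
    if chaos_all_draws:
        draw = lambda: np.array(  # noqa: E731
            [chaotic_uniform(stream) for _ in range(space.dim)]
        )
    _sco_loop(objective, space, config, state, history, rng, draw=draw)
    return OptimizationResult(
        gbest=state.gbest.copy(),
        f_gbest=state.f_gbest,
        history=np.asarray(history),
    )
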