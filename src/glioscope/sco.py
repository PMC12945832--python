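"""Single-candidate two-phase metaheuristic optimizer.

A single solution is evolved for a fixed budget of ``T`` objective
evaluations split into a global phase (multiplicative steps around the
incumbent best) and a local phase (bound-scaled steps), with a decaying
step weight, a stagnation-triggered full-range escape move, and a
reset-to-best boundary rule.  Acceptance is greedy: the incumbent is
replaced only on strict improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationError

__all__ = [
    "SearchSpace",
    "ScoConfig",
    "CandidateState",
    "OptimizationResult",
    "init_candidate",
    "weight_w",
    "phase1_step",
    "phase2_step",
    "escape_step",
    "clip_to_bounds",
    "run_sco",
]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box domain with finite bounds."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self):
        lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if lb.shape != ub.shape or lb.ndim != 1:
            raise ValueError("lb and ub must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
            raise ValueError("bounds must be finite")
        if not np.all(lb < ub):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def dim(self) -> int:
        return self.lb.shape[0]

    @property
    def width(self) -> np.ndarray:
        return self.ub - self.lb

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lb) and np.all(x <= self.ub))


@dataclass(frozen=True)
class ScoConfig:
    """Budget and schedule parameters.

    ``alpha_budget + beta_budget`` must equal the total evaluation budget
    ``T``.  ``b`` shapes the exponential weight decay, ``m`` is the number
    of consecutive non-improving evaluations that triggers the escape move.
    """

    T: int
    alpha_budget: int | None = None
    beta_budget: int | None = None
    b: float = 2.0
    m: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be a positive integer")
        a, be = self.alpha_budget, self.beta_budget
        if a is None and be is None:
            a = self.T // 2
            be = self.T - a
        elif a is None:
            a = self.T - be
        elif be is None:
            be = self.T - a
        if a < 0 or be < 0 or a + be != self.T:
            raise ValueError("alpha_budget + beta_budget must equal T")
        object.__setattr__(self, "alpha_budget", int(a))
        object.__setattr__(self, "beta_budget", int(be))
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.m < 1:
            raise ValueError("m must be a positive integer")


@dataclass
class CandidateState:
    """Bookkeeping for the single evolving candidate."""

    x: np.ndarray
    gbest: np.ndarray
    f_gbest: float
    c: int = 0
    p: int = 0
    t: int = 0


@dataclass
class OptimizationResult:
    gbest: np.ndarray
    f_gbest: float
    history: np.ndarray = field(repr=False)

    @property
    def n_evals(self) -> int:
        return len(self.history)


def init_candidate(space: SearchSpace, r4) -> np.ndarray:
    """Map uniform draws ``r4`` in [0, 1] onto the box: lb + r4*(ub-lb)."""
    r4 = np.asarray(r4, dtype=float)
    if r4.shape != (space.dim,):
        raise ValueError(f"r4 must have length {space.dim}, got shape {r4.shape}")
    if np.any(r4 < 0) or np.any(r4 > 1):
        raise ValueError("entries of r4 must lie in [0, 1]")
    return space.lb + r4 * space.width


def weight_w(t: float, config: ScoConfig) -> float:
    """Step weight exp(-(b*t/T)^b): 1 at t=0, strictly decreasing in t."""
    b = config.b
    return float(np.exp(-((b * t / config.T) ** b)))


def _branch(base, step, r):
    """Add ``step`` where r < 0.5, subtract it elsewhere (per dimension)."""
    r = np.asarray(r, dtype=float)
    return np.where(r < 0.5, base + step, base - step)


def phase1_step(gbest: np.ndarray, w: float, r1) -> np.ndarray:
    """Global phase: step of magnitude w*|gbest_j| in a random direction."""
    gbest = np.asarray(gbest, dtype=float)
    return _branch(gbest, w * np.abs(gbest), r1)


def phase2_step(gbest: np.ndarray, w: float, space: SearchSpace, r2, r_mag=None) -> np.ndarray:
    """Local phase: step of magnitude r*w*(ub_j-lb_j) in a random direction.

    ``r2`` selects the branch (step added where r2 < 0.5, subtracted
    elsewhere) and, when ``r_mag`` is omitted, also scales the step.
    The search loop passes an independent ``r_mag`` so that small steps
    are available in both directions; with a shared draw every downhill
    step has magnitude at least 0.5*w*(ub-lb), which stalls refinement.
    """
    gbest = np.asarray(gbest, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    mag = r2 if r_mag is None else np.asarray(r_mag, dtype=float)
    return _branch(gbest, mag * w * space.width, r2)


def escape_step(gbest: np.ndarray, space: SearchSpace, r3, r_mag=None) -> np.ndarray:
    """Stagnation escape: full-range step r*(ub_j-lb_j), no weight factor."""
    gbest = np.asarray(gbest, dtype=float)
    r3 = np.asarray(r3, dtype=float)
    mag = r3 if r_mag is None else np.asarray(r_mag, dtype=float)
    return _branch(gbest, mag * space.width, r3)


def clip_to_bounds(x: np.ndarray, gbest: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Replace any out-of-bounds dimension with the incumbent best value.

    Out-of-range coordinates are reset to ``gbest_j`` rather than clamped
    to the violated bound.
    """
    x = np.asarray(x, dtype=float)
    gbest = np.asarray(gbest, dtype=float)
    out = (x > space.ub) | (x < space.lb)
    return np.where(out, gbest, x)


def _evaluate(objective, x):
    f = float(objective(x))
    if not np.isfinite(f):
        raise EvaluationError(x, f)
    return f


def run_sco(objective, space: SearchSpace, config: ScoConfig) -> OptimizationResult:
    """Run the two-phase single-candidate search for ``config.T`` evaluations.

    The first evaluation is spent on the uniformly drawn initial candidate.
    History records the incumbent best objective value after every
    evaluation and is therefore monotone non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    x0 = init_candidate(space, rng.uniform(size=space.dim))
    state = CandidateState(x=x0, gbest=x0.copy(), f_gbest=_evaluate(objective, x0), t=1)
    history = [state.f_gbest]
    _sco_loop(objective, space, config, state, history, rng)
    return OptimizationResult(
        gbest=state.gbest.copy(),
        f_gbest=state.f_gbest,
        history=np.asarray(history),
    )


def _sco_loop(objective, space, config, state, history, rng, draw=None):
    """Shared evaluation loop; ``draw`` overrides the source of r1-r3 draws."""
    if draw is None:
        draw = lambda: rng.uniform(size=space.dim)  # noqa: E731
    while state.t < config.T:
        w = weight_w(state.t, config)
        if state.t < config.alpha_budget:
            x = phase1_step(state.gbest, w, draw())
        elif state.c >= config.m:
            # one full-range probe per stagnation episode; the counter
            # restarts afterwards so the local search resumes either way
            x = escape_step(state.gbest, space, draw(), r_mag=draw())
            state.c = 0
        else:
            x = phase2_step(state.gbest, w, space, draw(), r_mag=draw())
        x = clip_to_bounds(x, state.gbest, space)
        f = _evaluate(objective, x)
        state.x = x
        state.t += 1
        if f < state.f_gbest:  # strict improvement only; ties do not reset c
            state.gbest = x.copy()
            state.f_gbest = f
            state.p = 1
            state.c = 0
        else:
            state.p = 0
            state.c += 1
        history.append(state.f_gbest)
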