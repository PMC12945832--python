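"""Standard test objectives for optimizer validation (all minimized at 0)."""

from __future__ import annotations

import numpy as np

__all__ = ["sphere", "rastrigin", "rosenbrock", "BENCHMARKS"]


def sphere(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(
        np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
    )


BENCHMARKS = {"sphere": sphere, "rastrigin": rastrigin, "rosenbrock": rosenbrock}
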