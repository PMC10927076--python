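"""Classical benchmark test functions for continuous metaheuristic optimization.

The suite contains thirteen scalable functions: seven unimodal (F1-F7, probing
exploitation) and six multimodal (F8-F13, probing exploration).  Each function
has a scalar box constraint broadcast to every coordinate and a known global
minimum; all are symmetric in their coordinates.

Two functions deserve a note:

* F6 ("Step") ships in two variants.  The default is the classical floored
  De Jong step function ``sum(floor(x_i + 0.5)^2)``; a smooth variant
  ``sum((x_i + 0.5)^2)`` is selectable via ``step_variant="smooth"``.
* F7 ("Quartic Noise") adds a fresh uniform[0, 1) draw per evaluation and
  therefore requires a caller-supplied :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "BenchmarkFunction",
    "OutOfBoundsWarning",
    "benchmark_suite",
    "evaluate",
    "get",
    "global_minimum",
    "make_objective",
    "registry_frame",
    "write_registry",
    "SCHWEFEL_MINIMIZER",
    "SCHWEFEL_FMIN_PER_DIM",
]

#: 1-D minimizer of -x*sin(sqrt(|x|)) on [0, 500] (Schwefel 2.26, F8).
SCHWEFEL_MINIMIZER = 420.9687462275036

#: Per-dimension global minimum value of F8 at the printed table precision.
SCHWEFEL_FMIN_PER_DIM = -418.9829


class OutOfBoundsWarning(UserWarning):
    """Raised (as a warning) when a point outside the box is evaluated."""


def _f1(x):  # Sphere
    return float(np.sum(x * x))


def _f2(x):  # Schwefel 2.22
    ax = np.abs(x)
    return float(np.sum(ax) + np.prod(ax))


def _f3(x):  # Schwefel 1.20 (rotated hyper-ellipsoid)
    c = np.cumsum(x)
    return float(np.sum(c * c))


def _f4(x):  # Schwefel 2.21
    return float(np.max(np.abs(x)))


def _f5(x):  # Rosenbrock
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _f6_floored(x):  # Step (classical De Jong form)
    return float(np.sum(np.floor(x + 0.5) ** 2))


def _f6_smooth(x):  # Step, smooth variant (no floor)
    return float(np.sum((x + 0.5) ** 2))


def _f7(x, rng):  # Quartic with uniform noise
    i = np.arange(1, x.size + 1, dtype=float)
    return float(np.sum(i * x ** 4) + rng.random())


def _f8(x):  # Schwefel 2.26
    return float(np.sum(-x * np.sin(np.sqrt(np.abs(x)))))


def _f9(x):  # Rastrigin
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _f10(x):  # Ackley
    d = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + np.e
    )


def _f11(x):  # Griewank
    i = np.sqrt(np.arange(1, x.size + 1, dtype=float))
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / i)) + 1.0)


def _penalty(x, a, k, m):
    # piecewise boundary penalty: k(x-a)^m above a, 0 inside [-a, a],
    # k(-x-a)^m below -a
    out = np.zeros_like(x)
    hi = x > a
    lo = x < -a
    out[hi] = k * (x[hi] - a) ** m
    out[lo] = k * (-x[lo] - a) ** m
    return float(np.sum(out))


def _f12(x):  # Generalized penalized no. 1
    d = x.size
    y = 1.0 + (x + 1.0) / 4.0
    core = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(np.pi / d * core + _penalty(x, 10.0, 100.0, 4.0))


def _f13(x):  # Generalized penalized no. 2
    core = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return float(0.1 * core + _penalty(x, 10.0, 100.0, 4.0))


@dataclass(frozen=True)
class BenchmarkFunction:
    """One scalable test function with its box and known optimum."""

    id: str
    name: str
    modality: str  # "unimodal" | "multimodal"
    lower_bound: float
    upper_bound: float
    supported_dims: tuple = (30, 100)
    stochastic: bool = False

    def global_min_value(self, dim: int) -> float:
        """Known global minimum value at dimension ``dim``."""
        if self.id == "F8":
            return SCHWEFEL_FMIN_PER_DIM * dim
        return 0.0

    def minimizer(self, dim: int, step_variant: str = "floored") -> np.ndarray:
        """A known global minimizer at dimension ``dim``."""
        if self.id == "F5":
            return np.ones(dim)
        if self.id == "F6" and step_variant == "smooth":
            return np.full(dim, -0.5)
        if self.id == "F8":
            return np.full(dim, SCHWEFEL_MINIMIZER)
        if self.id == "F12":
            return -np.ones(dim)
        if self.id == "F13":
            return np.ones(dim)
        return np.zeros(dim)

    def evaluate(
        self,
        x: np.ndarray,
        rng: Optional[np.random.Generator] = None,
        step_variant: str = "floored",
    ) -> float:
        return evaluate(self.id, x, rng=rng, step_variant=step_variant)


_DETERMINISTIC: dict[str, Callable[[np.ndarray], float]] = {
    "F1": _f1,
    "F2": _f2,
    "F3": _f3,
    "F4": _f4,
    "F5": _f5,
    "F6": _f6_floored,
    "F8": _f8,
    "F9": _f9,
    "F10": _f10,
    "F11": _f11,
    "F12": _f12,
    "F13": _f13,
}

_SUITE: tuple[BenchmarkFunction, ...] = (
    BenchmarkFunction("F1", "Sphere", "unimodal", -100.0, 100.0),
    BenchmarkFunction("F2", "Schwefel's 2.22", "unimodal", -10.0, 10.0),
    BenchmarkFunction("F3", "Schwefel's 1.20", "unimodal", -100.0, 100.0),
    BenchmarkFunction("F4", "Schwefel's 2.21", "unimodal", -100.0, 100.0),
    BenchmarkFunction("F5", "Rosenbrock", "unimodal", -30.0, 30.0),
    BenchmarkFunction("F6", "Step", "unimodal", -100.0, 100.0),
    BenchmarkFunction("F7", "Quartic Noise", "unimodal", -1.28, 1.28, stochastic=True),
    BenchmarkFunction("F8", "Schwefel's 2.26", "multimodal", -500.0, 500.0),
    BenchmarkFunction("F9", "Rastrigin", "multimodal", -5.12, 5.12),
    BenchmarkFunction("F10", "Ackley", "multimodal", -32.0, 32.0),
    BenchmarkFunction("F11", "Griewank", "multimodal", -600.0, 600.0),
    BenchmarkFunction("F12", "Penalized", "multimodal", -50.0, 50.0),
    BenchmarkFunction("F13", "Generalized Penalized", "multimodal", -50.0, 50.0),
)

_BY_ID = {fn.id: fn for fn in _SUITE}


def benchmark_suite() -> list[BenchmarkFunction]:
    """Return the ordered thirteen-function suite (F1..F13)."""
    return list(_SUITE)


def get(fn_id: str) -> BenchmarkFunction:
    """Look up one function by id; raises ``KeyError`` for unknown ids."""
    try:
        return _BY_ID[fn_id]
    except KeyError:
        raise KeyError(f"unknown benchmark function id: {fn_id!r}") from None


def global_minimum(fn_id: str, dim: int) -> float:
    """Known global minimum value of ``fn_id`` at dimension ``dim``.

    Zero for every function except F8, whose minimum scales with dimension.
    """
    return get(fn_id).global_min_value(dim)


def evaluate(
    fn_id: str,
    x: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    step_variant: str = "floored",
) -> float:
    """Evaluate benchmark ``fn_id`` at point ``x``.

    ``x`` must be a 1-D real vector.  Points outside the function's box are
    evaluated anyway but flagged with :class:`OutOfBoundsWarning`.  F7 draws
    its additive noise from ``rng``, which is then required.
    """
    fn = get(fn_id)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError(
            f"{fn_id}: expected a non-empty 1-D vector, got shape {x.shape}"
        )
    if np.any(x < fn.lower_bound) or np.any(x > fn.upper_bound):
        warnings.warn(
            f"{fn_id} evaluated outside [{fn.lower_bound}, {fn.upper_bound}]",
            OutOfBoundsWarning,
            stacklevel=2,
        )
    if fn_id == "F7":
        if rng is None:
            raise ValueError("F7 requires a numpy Generator for its noise term")
        return _f7(x, rng)
    if fn_id == "F6" and step_variant == "smooth":
        return _f6_smooth(x)
    return _DETERMINISTIC[fn_id](x)


def make_objective(
    fn_id: str,
    rng: Optional[np.random.Generator] = None,
    step_variant: str = "floored",
) -> Callable[[np.ndarray], float]:
    """Close over a benchmark id (and noise stream for F7) as ``f(x) -> float``."""
    fn = get(fn_id)
    if fn.stochastic and rng is None:
        raise ValueError(f"{fn_id} is stochastic; pass a numpy Generator")

    def objective(x: np.ndarray) -> float:
        return evaluate(fn_id, x, rng=rng, step_variant=step_variant)

    objective.__name__ = f"{fn_id}_{fn.name.replace(' ', '_')}"
    return objective


def registry_frame() -> pd.DataFrame:
    """Machine-readable registry of the suite.

    Note: one published table prints F8's optimum as ``-148.9829*n``; the
    companion result tables use ``-418.9829*D``, the classical Schwefel value
    adopted here.
    """
    rows = [
        {
            "id": fn.id,
            "name": fn.name,
            "modality": fn.modality,
            "lb": fn.lower_bound,
            "ub": fn.upper_bound,
            "fmin_at_30": fn.global_min_value(30),
            "fmin_at_100": fn.global_min_value(100),
        }
        for fn in _SUITE
    ]
    return pd.DataFrame(rows)


def write_registry(path) -> None:
    """Write the suite registry as CSV."""
    registry_frame().to_csv(path, index=False)
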