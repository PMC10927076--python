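"""Whale optimization (WOA) and its discrete-recombination hybrid (RESHWOA).

WOA is a swarm metaheuristic in which each search agent ("whale") updates its
position relative to the incumbent best solution by one of three moves, chosen
stochastically each iteration:

* **encircling** (p < 0.5, |A| < 1): ``X <- X* - A * |C*X* - X|``
* **exploration** (p < 0.5, |A| >= 1): as above but relative to a randomly
  chosen agent instead of the elite
* **spiral / bubble-net** (p >= 0.5): ``X <- |X* - X| * exp(b*l) * cos(2*pi*l) + X*``

with ``A = 2*a*r1 - a`` and ``C = 2*r2``; the control parameter ``a`` decays
linearly from 2 to exactly 0 over the run, shifting the swarm from exploration
to exploitation.

RESHWOA replaces the uniform random initial population with offspring of a
discrete-recombination evolution strategy: each offspring coordinate is copied
from one of ``rho`` parents sampled without replacement from a ``mu``-sized
random pool (an analogue of uniform crossover).  Recombination is used for
initialization only — no mutation, no elitist selection — and every subsequent
iteration is standard WOA.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "OptimizerConfig",
    "Population",
    "OptimizationResult",
    "RunSummary",
    "a_schedule",
    "uniform_init",
    "dr_init",
    "intermediate_recombination",
    "woa_update",
    "run_woa",
    "run_reshwoa",
    "repeat_runs",
]


@dataclass
class OptimizerConfig:
    """All run parameters for WOA/RESHWOA.

    ``lb``/``ub`` may be scalars (broadcast to every coordinate) or
    per-dimension vectors.  ``mu``, ``lambda_`` and ``rho`` control the
    discrete-recombination initializer: pool size, offspring count, and
    parents per offspring.
    """

    dim: int
    lb: np.ndarray
    ub: np.ndarray
    n_agents: int = 30
    max_iter: int = 500
    spiral_b: float = 1.0
    init_mode: str = "uniform"  # "uniform" | "discrete_recombination"
    mu: int = 100
    lambda_: int = 100
    rho: int = 5
    dr_subset: str = "first"  # "first" | "best"
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        if self.n_agents < 1 or self.max_iter < 1:
            raise ValueError("n_agents and max_iter must be positive")
        lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.dim,)).copy()
        if np.any(lb >= ub):
            raise ValueError("lb must be elementwise strictly below ub")
        self.lb, self.ub = lb, ub
        if not (1 <= self.rho <= self.mu):
            raise ValueError(f"rho must satisfy 1 <= rho <= mu (got rho={self.rho}, mu={self.mu})")
        if self.lambda_ < 1 or self.mu < 1:
            raise ValueError("mu and lambda_ must be positive")
        if self.init_mode not in ("uniform", "discrete_recombination"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.dr_subset not in ("first", "best"):
            raise ValueError(f"unknown dr_subset {self.dr_subset!r}")


@dataclass
class Population:
    """Agent positions (n_agents x dim) and, once evaluated, their scores."""

    positions: np.ndarray
    scores: Optional[np.ndarray] = None


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_score: float
    convergence_curve: np.ndarray  # best-so-far score after each iteration
    elapsed_time: float
    seed: int


@dataclass
class RunSummary:
    """Aggregate of repeated independent runs (one benchmark-table row)."""

    label: str
    algorithm: str
    n_runs: int
    avg: float
    std: float
    avg_time: float
    best_scores: np.ndarray = field(repr=False, default=None)


def a_schedule(t: int, max_iter: int) -> float:
    """Linear decay of the contraction parameter: 2 at t=0, exactly 0 at t=max_iter."""
    return 2.0 * (1.0 - t / max_iter)


def uniform_init(config: OptimizerConfig, rng: Optional[np.random.Generator] = None) -> Population:
    """i.i.d. uniform positions on [lb, ub], one row per agent."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u = rng.random((config.n_agents, config.dim))
    return Population(config.lb + u * (config.ub - config.lb))


def dr_init(
    config: OptimizerConfig,
    rng: Optional[np.random.Generator] = None,
    return_all: bool = False,
) -> Population:
    """Discrete-recombination initial population.

    A pool of ``mu`` individuals is drawn uniformly on [0, 1]^dim.  Each of
    ``max(lambda_, n_agents)`` offspring samples ``rho`` parents without
    replacement from the pool and copies every coordinate from one of its
    parents, chosen uniformly per coordinate.  Offspring are scaled affinely
    to [lb, ub]; the first ``n_agents`` (or all, with ``return_all``) form
    the returned population.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu, rho, dim = config.mu, config.rho, config.dim
    lam = max(config.lambda_, config.n_agents)
    pool = rng.random((mu, dim))
    offspring = np.empty((lam, dim))
    cols = np.arange(dim)
    for o in range(lam):
        parents = rng.choice(mu, size=rho, replace=False)
        donor = rng.integers(0, rho, size=dim)
        offspring[o] = pool[parents[donor], cols]
    positions = config.lb + offspring * (config.ub - config.lb)
    if not return_all:
        positions = positions[: config.n_agents]
    return Population(positions)


def intermediate_recombination(parents: np.ndarray) -> np.ndarray:
    """Intermediate-recombination offspring: the coordinate-wise parent mean.

    Documented variant only; the hybrid initializer uses discrete
    recombination exclusively.
    """
    parents = np.asarray(parents, dtype=float)
    if parents.ndim != 2:
        raise ValueError("parents must be a 2-D (rho x dim) array")
    return parents.mean(axis=0)


def woa_update(
    positions: np.ndarray,
    best_position: np.ndarray,
    a: float,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
    spiral_b: float = 1.0,
) -> np.ndarray:
    """One synchronous WOA position update for the whole swarm.

    Per agent, four scalars are drawn in this order (vectorized over agents):
    ``r1``, ``r2``, ``p``, ``l`` (uniform on [-1, 1]), then an (n_agents x
    dim) block of random agent indices — the exploration move re-draws its
    reference whale per coordinate, which keeps exploration incoherent across
    dimensions.  Updated positions are clamped to [lb, ub].
    """
    n, dim = positions.shape
    r1 = rng.random(n)
    r2 = rng.random(n)
    p = rng.random(n)
    l = rng.uniform(-1.0, 1.0, n)
    rand_idx = rng.integers(0, n, (n, dim))

    A = 2.0 * a * r1 - a
    C = 2.0 * r2

    # reference point: elite when |A| < 1, a per-coordinate random agent otherwise
    use_best = np.abs(A) < 1.0
    ref = np.where(use_best[:, None], best_position[None, :], positions[rand_idx, np.arange(dim)])
    shrink = ref - A[:, None] * np.abs(C[:, None] * ref - positions)

    dist = np.abs(best_position[None, :] - positions)
    spiral = dist * (np.exp(spiral_b * l) * np.cos(2.0 * np.pi * l))[:, None] + best_position[None, :]

    new = np.where((p < 0.5)[:, None], shrink, spiral)
    return np.clip(new, lb, ub)


def _run(
    objective: Callable[[np.ndarray], float],
    config: OptimizerConfig,
    population: Population,
    rng: np.random.Generator,
) -> OptimizationResult:
    t0 = time.perf_counter()
    positions = population.positions.copy()

    def eval_all(pos):
        scores = np.array([objective(p) for p in pos], dtype=float)
        if not np.all(np.isfinite(scores)):
            bad = int(np.flatnonzero(~np.isfinite(scores))[0])
            raise ValueError(
                f"objective returned non-finite value {scores[bad]!r} at agent {bad}; "
                "run aborted"
            )
        return scores

    scores = eval_all(positions)
    best = int(np.argmin(scores))
    best_position = positions[best].copy()
    best_score = float(scores[best])

    curve = np.empty(config.max_iter)
    for t in range(1, config.max_iter + 1):
        a = a_schedule(t, config.max_iter)
        positions = woa_update(
            positions, best_position, a, config.lb, config.ub, rng, config.spiral_b
        )
        scores = eval_all(positions)
        i = int(np.argmin(scores))
        if scores[i] < best_score:  # strict improvement replaces the elite
            best_score = float(scores[i])
            best_position = positions[i].copy()
        curve[t - 1] = best_score

    return OptimizationResult(
        best_position=best_position,
        best_score=best_score,
        convergence_curve=curve,
        elapsed_time=time.perf_counter() - t0,
        seed=config.seed,
    )


def run_woa(
    objective: Callable[[np.ndarray], float],
    config: OptimizerConfig,
    initial_population: Optional[Population] = None,
) -> OptimizationResult:
    """Standard WOA with a uniform random initial population.

    ``initial_population`` overrides initialization (e.g. to seed a known
    point); it is not rescaled or clamped.
    """
    rng = np.random.default_rng(config.seed)
    pop = initial_population if initial_population is not None else uniform_init(config, rng)
    return _run(objective, config, pop, rng)


def run_reshwoa(
    objective: Callable[[np.ndarray], float],
    config: OptimizerConfig,
) -> OptimizationResult:
    """WOA seeded with a discrete-recombination initial population.

    Recombination affects only iteration zero; afterwards the dynamics are
    identical to :func:`run_woa`.  With ``dr_subset="best"`` the ``n_agents``
    best of the ``lambda_`` offspring (by objective value) seed the swarm
    instead of the first ``n_agents``.
    """
    rng = np.random.default_rng(config.seed)
    if config.dr_subset == "best":
        pop = dr_init(config, rng, return_all=True)
        scores = np.array([objective(p) for p in pop.positions], dtype=float)
        order = np.argsort(scores, kind="stable")[: config.n_agents]
        pop = Population(pop.positions[order])
    else:
        pop = dr_init(config, rng)
    return _run(objective, config, pop, rng)


_ALGORITHMS = {"WOA": run_woa, "RESHWOA": run_reshwoa}


def repeat_runs(
    objective: Optional[Callable[[np.ndarray], float]],
    config: OptimizerConfig,
    n_runs: int,
    algorithm: str = "WOA",
    label: str = "",
    objective_factory: Optional[Callable[[int], Callable[[np.ndarray], float]]] = None,
) -> RunSummary:
    """Aggregate ``n_runs`` independent runs; run ``k`` uses ``config.seed + k``.

    ``objective_factory(run_seed)`` may be supplied instead of ``objective``
    for stochastic objectives (e.g. F7) that need a per-run noise stream.
    ``avg``/``std`` are the sample mean and sample standard deviation of the
    per-run best scores (std is 0 for a single run).
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {sorted(_ALGORITHMS)}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if (objective is None) == (objective_factory is None):
        raise ValueError("pass exactly one of objective or objective_factory")
    runner = _ALGORITHMS[algorithm]

    bests = np.empty(n_runs)
    times = np.empty(n_runs)
    for k in range(n_runs):
        run_seed = config.seed + k
        cfg = OptimizerConfig(
            dim=config.dim,
            lb=config.lb,
            ub=config.ub,
            n_agents=config.n_agents,
            max_iter=config.max_iter,
            spiral_b=config.spiral_b,
            init_mode=config.init_mode,
            mu=config.mu,
            lambda_=config.lambda_,
            rho=config.rho,
            dr_subset=config.dr_subset,
            seed=run_seed,
        )
        obj = objective_factory(run_seed) if objective_factory is not None else objective
        result = runner(obj, cfg)
        bests[k] = result.best_score
        times[k] = result.elapsed_time

    std = 0.0 if n_runs == 1 else float(np.std(bests, ddof=1))
    return RunSummary(
        label=label,
        algorithm=algorithm,
        n_runs=n_runs,
        avg=float(np.mean(bests)),
        std=std,
        avg_time=float(np.mean(times)),
        best_scores=bests,
    )
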