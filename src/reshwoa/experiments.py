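"""Experiment drivers: benchmark tables and tuning tables, as CSV.

Outputs mirror the two kinds of result tables a metaheuristic comparison
produces: one row per (function, dimension, algorithm) with the mean/std/time
of repeated runs, and one row per (dataset, filter, optimizer) with the
min/avg/std holdout MSE and the best (C, gamma).  Every CSV starts with a
commented provenance header (package version, seed, config hash) so results
are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from reshwoa import benchmarks
from reshwoa.filtering import ExpressionDataset, reduce_dataset, run_filter
from reshwoa.optimizers import OptimizerConfig, repeat_runs
from reshwoa.svm_tuning import TuningConfig, tune

logger = logging.getLogger("reshwoa")

__all__ = ["ExperimentConfig", "run_benchmark_experiment", "run_tuning_experiment", "write_table"]

ALL_FUNCTIONS = tuple(fn.id for fn in benchmarks.benchmark_suite())


@dataclass
class ExperimentConfig:
    """Benchmark-table experiment parameters (defaults: full protocol)."""

    functions: Sequence[str] = ALL_FUNCTIONS
    dims: Sequence[int] = (30, 100)
    algorithms: Sequence[str] = ("WOA", "RESHWOA")
    n_runs: int = 30
    n_agents: int = 30
    max_iter: int = 500
    mu: int = 100
    lambda_: int = 100
    rho: int = 5
    seed: int = 0
    curves_dir: Optional[str] = None

    def __post_init__(self):
        if not self.functions or not self.dims or not self.algorithms:
            raise ValueError("functions, dims and algorithms must be non-empty")
        for f in self.functions:
            benchmarks.get(f)
        for a in self.algorithms:
            if a not in ("WOA", "RESHWOA"):
                raise ValueError(f"unknown algorithm {a!r}")


def _config_hash(obj) -> str:
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path, seed: int, config) -> None:
    """Write a CSV with a commented provenance header."""
    from reshwoa import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# reshwoa v{__version__}\n")
        fh.write(f"# seed={seed} config_hash={_config_hash(config)}\n")
        frame.to_csv(fh, index=False)


def run_benchmark_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """One row per (function, dim, algorithm): avg/std/avg_time of best scores.

    With ``curves_dir`` set, the best-so-far convergence curve of the first
    run in each cell is written as ``<id>_D<dim>_<algo>.csv``.
    """
    rows = []
    for fn_id in config.functions:
        fn = benchmarks.get(fn_id)
        for dim in config.dims:
            for algo in config.algorithms:
                cfg = OptimizerConfig(
                    dim=dim,
                    lb=fn.lower_bound,
                    ub=fn.upper_bound,
                    n_agents=config.n_agents,
                    max_iter=config.max_iter,
                    mu=config.mu,
                    lambda_=config.lambda_,
                    rho=config.rho,
                    seed=config.seed,
                )
                if fn.stochastic:
                    factory = lambda s: benchmarks.make_objective(
                        fn_id, rng=np.random.default_rng(s)
                    )
                    summary = repeat_runs(
                        None, cfg, config.n_runs, algorithm=algo, label=fn_id,
                        objective_factory=factory,
                    )
                else:
                    summary = repeat_runs(
                        benchmarks.make_objective(fn_id), cfg, config.n_runs,
                        algorithm=algo, label=fn_id,
                    )
                logger.info(
                    "%s D=%d %s: avg=%.6g std=%.6g (%d runs)",
                    fn_id, dim, algo, summary.avg, summary.std, summary.n_runs,
                )
                rows.append(
                    {
                        "function": fn_id,
                        "name": fn.name,
                        "dim": dim,
                        "algorithm": algo,
                        "avg": summary.avg,
                        "std": summary.std,
                        "avg_time": summary.avg_time,
                        "benchmark": fn.global_min_value(dim),
                    }
                )
                if config.curves_dir is not None:
                    from reshwoa.optimizers import run_reshwoa, run_woa

                    runner = run_reshwoa if algo == "RESHWOA" else run_woa
                    obj = (
                        benchmarks.make_objective(fn_id, rng=np.random.default_rng(cfg.seed))
                        if fn.stochastic
                        else benchmarks.make_objective(fn_id)
                    )
                    curve = runner(obj, cfg).convergence_curve
                    out = Path(config.curves_dir) / f"{fn_id}_D{dim}_{algo}.csv"
                    out.parent.mkdir(parents=True, exist_ok=True)
                    pd.DataFrame(
                        {"iteration": np.arange(1, curve.size + 1), "best_so_far": curve}
                    ).to_csv(out, index=False)
    return pd.DataFrame(rows)


def run_tuning_experiment(
    datasets: dict[str, ExpressionDataset],
    tuning: TuningConfig,
    filter_method: str = "SNR",
    k: int = 20,
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Filter each dataset, tune the SVM on the reduced genes, emit one row each.

    The log records the selected gene count and the selected/total ratio for
    every dataset.
    """
    rows = []
    for name, dataset in datasets.items():
        t0 = time.perf_counter()
        fres = run_filter(dataset, filter_method, k=k, threshold=threshold)
        reduced = reduce_dataset(dataset, fres)
        ratio = 100.0 * reduced.n_genes / dataset.n_genes
        logger.info(
            "%s: %s selected %d/%d genes (%.2f%%)",
            name, filter_method, reduced.n_genes, dataset.n_genes, ratio,
        )
        result = tune(reduced, tuning)
        rows.append(
            {
                "dataset": name,
                "filter": filter_method.upper(),
                "optimizer": tuning.optimizer,
                "n_selected": reduced.n_genes,
                "ratio_pct": ratio,
                "C": result.best_params[0],
                "gamma": result.best_params[1],
                "min_mse": result.min_mse,
                "avg_mse": result.avg_mse,
                "std_mse": result.std_mse,
                "elapsed": time.perf_counter() - t0,
            }
        )
    return pd.DataFrame(rows)
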