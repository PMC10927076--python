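"""RBF-SVM hyperparameter search by whale optimization.

The classifier is a support-vector machine with radial-basis kernel; its
penalty C and kernel width gamma are searched in a 2-D box by WOA or RESHWOA,
using the mean squared error of hard-label predictions on a held-out test
split as the fitness.  For 0/1-encoded labels this MSE equals the test
misclassification rate.

Protocol: per independent run, one stratified 70/30 holdout split is drawn
from the run seed (so run-to-run spread reflects both split and optimizer
noise; ``fixed_split`` freezes the split across runs), the optimizer runs a
short budget (default 50 iterations, 30 agents), and the per-run best MSEs
are aggregated as min/avg/std.  Default search box: C in [0.0001, 10],
gamma in [0.1, 100]; a wider trial box (C up to 100, gamma from 0.001 to 50)
is available as :data:`WIDE_BOUNDS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from reshwoa.filtering import ExpressionDataset
from reshwoa.optimizers import OptimizerConfig, run_reshwoa, run_woa

__all__ = [
    "DEFAULT_ENCODING",
    "WIDE_BOUNDS",
    "LabelEncoding",
    "TuningConfig",
    "TuningResult",
    "encode_labels",
    "holdout_split",
    "svm_mse_objective",
    "tune",
]

#: Default categorical -> numeric label mapping.
DEFAULT_ENCODING = {"Tumour": 1, "Normal": 0}

#: Alternative, wider (C, gamma) search box: C in [1e-4, 100], gamma in [1e-3, 50].
WIDE_BOUNDS = {"c_bounds": (1e-4, 100.0), "gamma_bounds": (1e-3, 50.0)}

LabelEncoding = dict


@dataclass
class TuningConfig:
    c_bounds: tuple = (1e-4, 10.0)
    gamma_bounds: tuple = (0.1, 100.0)
    holdout_fraction: float = 0.3
    optimizer: str = "RESHWOA"  # "WOA" | "RESHWOA"
    n_agents: int = 30
    max_iter: int = 50
    n_runs: int = 30
    mu: int = 100
    lambda_: int = 100
    rho: int = 5
    fixed_split: bool = False
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in (("c_bounds", self.c_bounds), ("gamma_bounds", self.gamma_bounds)):
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (lo < hi), got {(lo, hi)}")
            if lo <= 0:
                raise ValueError(f"{name} must be positive for an RBF SVM")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.optimizer not in ("WOA", "RESHWOA"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TuningResult:
    best_params: tuple  # (C, gamma) at the overall-minimum MSE
    min_mse: float
    avg_mse: float
    std_mse: float
    per_run: list = field(repr=False)  # [(C, gamma, best_mse), ...]


def encode_labels(labels, encoding: Optional[LabelEncoding] = None) -> np.ndarray:
    """Map categorical labels to numbers, preserving order.

    Unknown labels raise a ``KeyError`` naming the offending value.
    """
    if encoding is None:
        encoding = DEFAULT_ENCODING
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        if lab not in encoding:
            raise KeyError(
                f"label {lab!r} not in encoding {sorted(encoding)}; "
                "pass an explicit LabelEncoding"
            )
        out[i] = encoding[lab]
    return out


def infer_encoding(dataset: ExpressionDataset) -> LabelEncoding:
    """Default mapping for a dataset: Tumour/Normal if present, else the
    lexicographically first class -> 1 and the other -> 0."""
    names = dataset.class_names()
    if set(names) <= set(DEFAULT_ENCODING):
        return dict(DEFAULT_ENCODING)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 classes, found {names}")
    return {names[0]: 1, names[1]: 0}


def holdout_split(
    dataset: ExpressionDataset, test_fraction: float = 0.3, seed: int = 0
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified disjoint train/test partition with round(frac * n) test samples."""
    n = dataset.n_samples
    n_test = int(round(test_fraction * n))
    if not 0 < n_test < n:
        raise ValueError(f"test_fraction {test_fraction} leaves an empty split for n={n}")
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=n_test, random_state=seed, stratify=dataset.labels
    )
    train, test = dataset.subset_samples(train_idx), dataset.subset_samples(test_idx)
    for part, name in ((train, "train"), (test, "test")):
        if len(part.class_names()) != 2:
            raise ValueError(f"{name} split lost a class; use a larger split or dataset")
    return train, test


def svm_mse_objective(
    params,
    train: ExpressionDataset,
    test: ExpressionDataset,
    encoding: Optional[LabelEncoding] = None,
) -> float:
    """Holdout MSE of an RBF SVC with penalty C and kernel width gamma.

    Features are z-scored with train-split statistics (applied unchanged to
    the test split); predictions are hard labels, so with a 0/1 encoding the
    MSE is the test misclassification rate.
    """
    c, gamma = float(params[0]), float(params[1])
    if c <= 0 or gamma <= 0:
        raise ValueError(f"C and gamma must be positive, got ({c}, {gamma})")
    if encoding is None:
        encoding = infer_encoding(train)
    y_train = encode_labels(train.labels, encoding)
    y_test = encode_labels(test.labels, encoding)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")

    mean = train.matrix.mean(axis=0)
    sd = train.matrix.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    x_train = (train.matrix - mean) / sd
    x_test = (test.matrix - mean) / sd

    model = SVC(C=c, gamma=gamma, kernel="rbf")
    model.fit(x_train, y_train)
    pred = model.predict(x_test)
    return float(np.mean((y_test - pred) ** 2))


def tune(
    dataset: ExpressionDataset,
    config: TuningConfig,
    encoding: Optional[LabelEncoding] = None,
) -> TuningResult:
    """Search the (C, gamma) box minimizing holdout MSE, over repeated runs.

    Run ``k`` derives its seed as ``config.seed + k``; that seed fixes both
    the holdout split (unless ``fixed_split``) and the optimizer stream.
    """
    if encoding is None:
        encoding = infer_encoding(dataset)
    runner = run_reshwoa if config.optimizer == "RESHWOA" else run_woa
    lb = np.array([config.c_bounds[0], config.gamma_bounds[0]])
    ub = np.array([config.c_bounds[1], config.gamma_bounds[1]])

    per_run = []
    for k in range(config.n_runs):
        run_seed = config.seed + k
        split_seed = config.seed if config.fixed_split else run_seed
        train, test = holdout_split(dataset, config.holdout_fraction, split_seed)

        def objective(params):
            return svm_mse_objective(params, train, test, encoding)

        opt_cfg = OptimizerConfig(
            dim=2,
            lb=lb,
            ub=ub,
            n_agents=config.n_agents,
            max_iter=config.max_iter,
            mu=config.mu,
            lambda_=config.lambda_,
            rho=config.rho,
            seed=run_seed,
        )
        result = runner(objective, opt_cfg)
        per_run.append((float(result.best_position[0]), float(result.best_position[1]),
                        float(result.best_score)))

    mses = np.array([r[2] for r in per_run])
    best = int(np.argmin(mses))
    std = 0.0 if config.n_runs == 1 else float(np.std(mses, ddof=1))
    return TuningResult(
        best_params=(per_run[best][0], per_run[best][1]),
        min_mse=float(mses[best]),
        avg_mse=float(np.mean(mses)),
        std_mse=std,
        per_run=per_run,
    )
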