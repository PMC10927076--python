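"""Two-class microarray-like expression data with planted differential genes.

The generator emulates the shape of classic two-class cancer expression
studies: tens of samples, thousands of genes, and a small planted set of
differentially expressed genes.  Noise genes are Gaussian with identical
parameters in both classes; informative genes receive a mean shift of
``effect_size * within_sd`` in class 1, with alternating sign across the
planted genes so both over- and under-expression occur.  An optional
heteroscedastic mode inflates the class-1 sd of planted genes, which
exercises the variance-sensitive log term of the Bhattacharyya filter.

Shape presets named after well-known public datasets ("colon-like" = 62
samples x 2000 genes, etc.) keep tests honest about the n << p regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from reshwoa.filtering import ExpressionDataset

__all__ = ["SyntheticSpec", "PRESETS", "preset_spec", "generate", "write_dataset", "read_dataset"]

#: (n_class1, n_class2, n_genes) shape presets mirroring classic studies.
PRESETS = {
    "breast-like": (46, 51, 24481),
    "carcinoma-like": (18, 18, 7464),
    "colon-like": (40, 22, 2000),
    "cns-like": (21, 39, 7129),
    "ovarian-like": (162, 91, 15154),
    "leukemia-like": (47, 25, 7129),
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the class-1 mean shift of planted genes in units of
    ``within_sd``; ``class1_sd_scale`` > 1 makes planted genes
    heteroscedastic (class-1 sd inflated by that factor).
    """

    n_class1: int = 30
    n_class2: int = 30
    n_genes: int = 2000
    n_informative: int = 20
    effect_size: float = 2.0
    within_sd: float = 1.0
    baseline_mean: float = 8.0
    class1_sd_scale: float = 1.0
    label_names: tuple = ("Tumour", "Normal")
    seed: int = 0

    def __post_init__(self):
        if self.n_class1 < 2 or self.n_class2 < 2:
            raise ValueError("both classes need at least 2 samples")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ValueError("n_informative must lie in [0, n_genes]")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        if self.class1_sd_scale <= 0:
            raise ValueError("class1_sd_scale must be positive")


def preset_spec(name: str, **overrides) -> SyntheticSpec:
    """A :class:`SyntheticSpec` with the shape of a named preset."""
    try:
        n1, n2, g = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return SyntheticSpec(n_class1=n1, n_class2=n2, n_genes=g, **overrides)


def generate(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw one dataset; planted gene indices land in ``metadata["informative"]``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_class1 + spec.n_class2
    matrix = rng.normal(spec.baseline_mean, spec.within_sd, size=(n, spec.n_genes))

    informative = np.sort(rng.choice(spec.n_genes, size=spec.n_informative, replace=False))
    signs = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)
    c1 = slice(0, spec.n_class1)
    matrix[c1, informative] += signs * spec.effect_size * spec.within_sd
    if spec.class1_sd_scale != 1.0 and spec.n_informative:
        extra_sd = spec.within_sd * np.sqrt(max(spec.class1_sd_scale ** 2 - 1.0, 0.0))
        matrix[c1, informative] += rng.normal(
            0.0, extra_sd, size=(spec.n_class1, spec.n_informative)
        )

    labels = np.array(
        [spec.label_names[0]] * spec.n_class1 + [spec.label_names[1]] * spec.n_class2
    )
    width = len(str(spec.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    return ExpressionDataset(
        matrix,
        labels,
        gene_ids,
        sample_ids,
        metadata={"informative": informative, "spec": spec},
    )


def write_dataset(dataset: ExpressionDataset, path) -> None:
    """Write as CSV: one row per sample, a ``y`` label column, gene columns."""
    frame = pd.DataFrame(dataset.matrix, columns=dataset.gene_ids, index=dataset.sample_ids)
    frame.insert(0, "y", dataset.labels)
    frame.to_csv(path, index_label="sample_id")


def read_dataset(path, label_column: str = "y") -> ExpressionDataset:
    """Read the CSV dialect of :func:`write_dataset`.

    Raises a ``ValueError`` locating the offending row/column for a missing
    label column, a non-numeric expression cell, or an empty gene set.
    """
    frame = pd.read_csv(path, index_col=0)
    if label_column not in frame.columns:
        raise ValueError(f"{path}: missing label column {label_column!r}")
    labels = frame[label_column].astype(str).to_numpy()
    genes = frame.drop(columns=[label_column])
    if genes.shape[1] == 0:
        raise ValueError(f"{path}: no gene columns found")
    for col in genes.columns:
        coerced = pd.to_numeric(genes[col], errors="coerce")
        bad = coerced.isna() & genes[col].notna()
        if genes[col].isna().any() or bad.any():
            row = genes.index[(genes[col].isna() | bad)][0]
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row!r}, column {col!r}"
            )
        genes[col] = coerced
    return ExpressionDataset(
        genes.to_numpy(dtype=float),
        labels,
        [str(c) for c in genes.columns],
        [str(i) for i in genes.index],
    )
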