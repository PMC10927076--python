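"""Per-gene two-class filter statistics for expression matrices.

Microarray studies measure thousands of genes on tens of samples; before any
classifier is fit, genes are ranked by a univariate statistic contrasting the
two phenotype classes.  Two filters are provided:

* **signal-to-noise ratio (SNR)**: ``(mu1 - mu2) / (sigma1 + sigma2)`` with
  class-wise sample means and standard deviations.  Antisymmetric under a
  class swap; genes are selected by absolute value so over- and
  under-expressed markers rank symmetrically.
* **Bhattacharyya distance (BC)**: the univariate Gaussian form

  ``B = (mu_i - mu_j)^2 / (8 * (s_i^2 + s_j^2) / 2)
      + 0.5 * ln(((s_i^2 + s_j^2) / 2) / (s_i * s_j))``

  a nonnegative divergence between the two class distributions, symmetric
  under a class swap; it also responds to variance differences through the
  log term.

Selection is top-k for SNR (default k = 20) and threshold-based for BC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ExpressionDataset",
    "FilterResult",
    "normalize",
    "snr_scores",
    "bhattacharyya_scores",
    "select_top_k",
    "select_by_threshold",
    "reduce_dataset",
    "run_filter",
]


@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with binary class labels.

    ``labels`` holds the semantic class names (e.g. "Tumour"/"Normal");
    class roles follow sorted label order (class 1 = lexicographically first),
    so relabeling samples exchanges the roles deterministically.
    ``metadata`` may record provenance such as planted informative genes.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_ids: list
    sample_ids: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x genes)")
        n, g = self.matrix.shape
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} genes")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} samples")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def class_names(self) -> list:
        """The distinct labels in sorted order (class 1 first)."""
        return sorted(set(self.labels.tolist()))

    def class_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean sample masks for the two classes; errors unless exactly two."""
        names = self.class_names()
        if len(names) != 2:
            raise ValueError(f"expected exactly 2 classes, found {names}")
        return self.labels == names[0], self.labels == names[1]

    def subset_samples(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            self.matrix[idx],
            self.labels[idx],
            list(self.gene_ids),
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
            dict(self.metadata),
        )

    def subset_genes(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            self.matrix[:, idx],
            self.labels,
            [self.gene_ids[i] for i in np.atleast_1d(idx)],
            list(self.sample_ids),
            dict(self.metadata),
        )


@dataclass
class FilterResult:
    method: str  # "SNR" | "BC"
    scores: np.ndarray
    selected: np.ndarray  # indices into gene_ids, sorted by descending criterion
    params: dict


def normalize(dataset: ExpressionDataset, method: str = "zscore") -> ExpressionDataset:
    """Per-gene normalization across all samples.

    ``zscore`` (default) maps each gene to zero mean / unit sd; constant genes
    map to all-zeros.  ``minmax`` rescales to [0, 1] (constant genes to 0);
    ``none`` is the identity.
    """
    if method == "none":
        return dataset
    m = dataset.matrix
    if method == "zscore":
        mean = m.mean(axis=0)
        sd = m.std(axis=0)
        out = np.where(sd > 0, (m - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    elif method == "minmax":
        lo, hi = m.min(axis=0), m.max(axis=0)
        span = hi - lo
        out = np.where(span > 0, (m - lo) / np.where(span > 0, span, 1.0), 0.0)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return ExpressionDataset(
        out, dataset.labels, list(dataset.gene_ids), list(dataset.sample_ids), dict(dataset.metadata)
    )


def _class_stats(dataset: ExpressionDataset):
    m1, m2 = dataset.class_masks()
    names = dataset.class_names()
    for mask, name in ((m1, names[0]), (m2, names[1])):
        if mask.sum() < 2:
            raise ValueError(
                f"class {name!r} has {int(mask.sum())} sample(s); need >= 2 for a sample sd"
            )
    x1, x2 = dataset.matrix[m1], dataset.matrix[m2]
    return (
        x1.mean(axis=0),
        x2.mean(axis=0),
        x1.std(axis=0, ddof=1),
        x2.std(axis=0, ddof=1),
    )


def snr_scores(dataset: ExpressionDataset) -> np.ndarray:
    """Signal-to-noise ratio (mu1 - mu2)/(sigma1 + sigma2) per gene.

    When both class sds are zero the gene carries no within-class noise: the
    score is 0 if the means also agree, otherwise the largest finite float
    with the sign of the mean difference (a sentinel that sorts above every
    regular gene).
    """
    mu1, mu2, sd1, sd2 = _class_stats(dataset)
    num = mu1 - mu2
    den = sd1 + sd2
    big = np.finfo(float).max
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.sign(num) * big)
    return scores


def bhattacharyya_scores(dataset: ExpressionDataset) -> np.ndarray:
    """Univariate Gaussian Bhattacharyya distance per gene (always >= 0)."""
    mu1, mu2, sd1, sd2 = _class_stats(dataset)
    zero = (sd1 == 0) | (sd2 == 0)
    if np.any(zero):
        bad = [dataset.gene_ids[i] for i in np.flatnonzero(zero)[:5]]
        raise ValueError(
            f"zero within-class variance for gene(s) {bad}; "
            "Bhattacharyya distance is undefined"
        )
    v = (sd1 ** 2 + sd2 ** 2) / 2.0
    return 0.125 * (mu1 - mu2) ** 2 / v + 0.5 * np.log(v / (sd1 * sd2))


def select_top_k(scores: np.ndarray, k: int = 20) -> np.ndarray:
    """Indices of the k largest-|score| genes, descending; ties by lower index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-np.abs(scores), kind="stable")
    return order[: min(k, scores.size)]


def select_by_threshold(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Indices with score strictly above ``threshold``, sorted descending."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    hits = np.flatnonzero(scores > threshold)
    order = np.argsort(-scores[hits], kind="stable")
    return hits[order]


def run_filter(
    dataset: ExpressionDataset,
    method: str,
    k: int = 20,
    threshold: Optional[float] = None,
    normalization: str = "zscore",
) -> FilterResult:
    """Normalize, score, and select genes with one filter.

    SNR selects the top ``k`` genes by |score|; BC selects either by
    ``threshold`` (strictly greater) or, when ``threshold`` is None, by
    top ``k`` score — the threshold has to be set per dataset by inspection,
    so a rank-based fallback is provided.
    """
    method = method.upper()
    normalized = normalize(dataset, normalization)
    if method == "SNR":
        scores = snr_scores(normalized)
        selected = select_top_k(scores, k)
        params = {"k": k, "normalization": normalization}
    elif method == "BC":
        scores = bhattacharyya_scores(normalized)
        if threshold is not None:
            selected = select_by_threshold(scores, threshold)
            params = {"threshold": threshold, "normalization": normalization}
        else:
            selected = np.argsort(-scores, kind="stable")[: min(k, scores.size)]
            params = {"k": k, "normalization": normalization}
    else:
        raise ValueError(f"unknown filter method {method!r}; expected 'SNR' or 'BC'")
    return FilterResult(method=method, scores=scores, selected=selected, params=params)


def reduce_dataset(dataset: ExpressionDataset, result: FilterResult) -> ExpressionDataset:
    """Restrict ``dataset`` to the genes a filter selected (original values)."""
    return dataset.subset_genes(result.selected)
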