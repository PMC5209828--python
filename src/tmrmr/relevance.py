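"""Gene relevance: per-timestep one-way ANOVA F-statistics aggregated across time.

For gene j at time t the one-way F compares the K class means of the
expression slice across the N subjects:

    F = [sum_k n_k (mean_k - grand_mean)^2 / (K-1)]
        / [sum_k sum_l (x_lk - mean_k)^2 / (N-K)]

and the gene's relevance is an aggregate of the T per-time values —
by default the arithmetic mean; median, geometric mean and maximum are
available as alternatives.

Degenerate slices: zero within-class variance with separated class means
yields the ``inf`` sentinel (sorts above every finite score); an entirely
constant slice yields 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import GeneTrajectoryMatrix, TemporalDataset

__all__ = [
    "RelevanceProfile",
    "f_statistic_at_time",
    "f_statistics_tensor",
    "gene_relevance",
    "relevance_all",
    "aggregate",
    "rank_by_relevance",
    "AGGREGATORS",
]

AGGREGATORS = ("mean", "median", "geometric_mean", "max")


@dataclass(frozen=True)
class RelevanceProfile:
    """Per-time F values and their aggregate for one gene."""

    gene_id: str
    per_time_F: np.ndarray
    aggregate_F: float
    aggregator: str


def _class_matrix(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-hot class indicator (N x K) and class sizes n_k."""
    labels = np.asarray(labels, dtype=int)
    k = labels.max()
    if k < 2:
        raise ValueError("need at least 2 classes")
    onehot = np.zeros((labels.size, k))
    onehot[np.arange(labels.size), labels - 1] = 1.0
    nk = onehot.sum(axis=0)
    if (nk == 0).any():
        raise ValueError("every class 1..K must be non-empty")
    return onehot, nk


def f_statistics_tensor(expression: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way F for every (gene, time) slice of an (N, G, T) tensor at once.

    Returns a (G, T) array.  Vectorized sum-of-squares decomposition:
    between-class SS from class means, within-class SS as total minus between.
    """
    x = np.asarray(expression, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = x.shape[0]
    onehot, nk = _class_matrix(labels)
    k = nk.size
    if n <= k:
        raise ValueError("need N > K for a finite within-class denominator")
    grand = x.mean(axis=0)  # (G, T)
    class_sums = np.einsum("nk,ngt->kgt", onehot, x)
    class_means = class_sums / nk[:, None, None]
    ss_between = np.einsum("k,kgt->gt", nk, (class_means - grand[None]) ** 2)
    # within-SS computed directly (not as total minus between) to avoid
    # cancellation when class separation dwarfs the residual variance
    ss_within = ((x - class_means[labels - 1]) ** 2).sum(axis=0)
    num = ss_between / (k - 1)
    den = ss_within / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    # den == 0: separated classes -> inf sentinel; fully constant slice -> 0
    f = np.where(den > 0, f, np.where(num > 0, np.inf, 0.0))
    return f


def f_statistic_at_time(slice_values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F of a single length-N expression slice against the labels."""
    x = np.asarray(slice_values, dtype=float).reshape(-1, 1, 1)
    return float(f_statistics_tensor(x, labels)[0, 0])


def aggregate(per_time_F: np.ndarray, aggregator: str = "mean") -> float:
    """Collapse the T per-time F values into one relevance score."""
    f = np.asarray(per_time_F, dtype=float)
    if aggregator == "mean":
        return float(f.mean())
    if aggregator == "median":
        return float(np.median(f))
    if aggregator == "max":
        return float(f.max())
    if aggregator == "geometric_mean":
        if (f == 0).any():
            return 0.0  # log-limit convention
        if np.isinf(f).any():
            return np.inf
        return float(np.exp(np.mean(np.log(f))))
    raise ValueError(f"unknown aggregator {aggregator!r}; choose from {AGGREGATORS}")


def gene_relevance(
    gene: GeneTrajectoryMatrix, labels: np.ndarray, aggregator: str = "mean"
) -> RelevanceProfile:
    """Relevance profile of one gene: per-time F vector plus its aggregate."""
    per_time = f_statistics_tensor(gene.values[:, None, :], labels)[0]
    return RelevanceProfile(gene.gene_id, per_time, aggregate(per_time, aggregator), aggregator)


def relevance_all(
    ds: TemporalDataset, aggregator: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate relevance for every gene.

    Returns ``(per_time_F, aggregate_F)`` with shapes (G, T) and (G,).
    """
    per_time = f_statistics_tensor(ds.expression, ds.labels)
    agg = np.array([aggregate(per_time[j], aggregator) for j in range(per_time.shape[0])])
    return per_time, agg


def rank_by_relevance(relevances: np.ndarray) -> np.ndarray:
    """Gene indices sorted by descending relevance; ties by ascending index.

    ``inf`` sentinels sort above all finite values (and among themselves by
    ascending index), so the ordering is total and bit-reproducible.
    """
    r = np.asarray(relevances, dtype=float)
    # lexsort: last key is primary; -r puts inf first, stable index tie-break
    return np.lexsort((np.arange(r.size), -r))
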