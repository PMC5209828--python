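"""DTW-based redundancy between gene expression trajectories.

Redundancy between two genes is the reciprocal of a mean dynamic-time-warping
distance between their per-subject trajectories, computed after z-scoring each
trajectory so that only *shape* matters (offsets and amplitudes are removed).
Two reductions of the N x N cross-subject distance matrix D are supported:

* ``C`` (TMRMR-C): reciprocal of the mean over all N^2 entries of D;
* ``M`` (TMRMR-M): reciprocal of the mean over the N diagonal entries
  (matched subjects only) — O(N) DTW calls per gene pair instead of O(N^2).

DTW here is the exact dynamic program with absolute-difference local cost,
unit-weighted steps (1,0), (0,1), (1,1), boundary-matched paths and no
warping window.  For the equal-length trajectories of a dataset the dynamic
program is vectorized across all subject pairs at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import GeneTrajectoryMatrix

__all__ = [
    "EPS",
    "PairDistanceMatrix",
    "RedundancyMatrix",
    "zscore_trajectory",
    "zscore_rows",
    "dtw_distance",
    "dtw_pairwise",
    "dtw_paired",
    "pair_distance_matrix",
    "redundancy",
    "pair_redundancy",
    "pool_redundancy_matrix",
    "RedundancyCache",
]

# floor for mean DTW distance before taking the reciprocal: identical
# normalized trajectories give a large finite redundancy, not infinity
EPS = 1e-12


@dataclass(frozen=True)
class PairDistanceMatrix:
    """N x N DTW distances for one gene pair; entry (p, q) compares subject
    p's trajectory of gene i with subject q's trajectory of gene j."""

    D: np.ndarray
    gene_pair: tuple[str, str]


@dataclass(frozen=True)
class RedundancyMatrix:
    """Symmetric pairwise redundancies over a candidate pool."""

    R: np.ndarray
    gene_ids: tuple[str, ...]
    variant: str


def zscore_trajectory(traj: np.ndarray) -> np.ndarray:
    """Center and scale one trajectory to mean 0, population sd 1.

    A constant trajectory has no shape; it maps to the all-zero vector.
    """
    t = np.asarray(traj, dtype=float)
    mu = t.mean()
    sigma = t.std()  # population convention (divide by T)
    if sigma == 0:
        return np.zeros_like(t)
    return (t - mu) / sigma


def zscore_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise z-scoring of an N x T trajectory matrix."""
    m = np.asarray(matrix, dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sigma = m.std(axis=1, keepdims=True)
    safe = np.where(sigma > 0, sigma, 1.0)
    return np.where(sigma > 0, (m - mu) / safe, 0.0)


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Exact DTW distance between two sequences (may differ in length)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty sequences")
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.empty_like(cost)
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    acc[1:, 0] = cost[1:, 0].cumsum() + cost[0, 0]
    for u in range(1, a.size):
        for v in range(1, b.size):
            acc[u, v] = cost[u, v] + min(acc[u - 1, v], acc[u, v - 1], acc[u - 1, v - 1])
    return float(acc[-1, -1])


def _dtw_batch(cost: np.ndarray) -> np.ndarray:
    """Run the DTW dynamic program over a (..., T, T) local-cost array."""
    t1, t2 = cost.shape[-2:]
    acc = np.empty_like(cost)
    acc[..., 0, 0] = cost[..., 0, 0]
    acc[..., 0, 1:] = np.cumsum(cost[..., 0, 1:], axis=-1) + cost[..., 0, :1]
    acc[..., 1:, 0] = np.cumsum(cost[..., 1:, 0], axis=-1) + cost[..., :1, 0]
    for u in range(1, t1):
        for v in range(1, t2):
            best = np.minimum(acc[..., u - 1, v], acc[..., u, v - 1])
            np.minimum(best, acc[..., u - 1, v - 1], out=best)
            acc[..., u, v] = cost[..., u, v] + best
    return acc[..., -1, -1]


def dtw_pairwise(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs DTW between rows of A (na x T) and rows of B (nb x T)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    cost = np.abs(A[:, None, :, None] - B[None, :, None, :])
    return _dtw_batch(cost)


def dtw_paired(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-matched DTW: vector of dtw(A[p], B[p]) for p = 1..N."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("matched DTW needs equal-shape matrices")
    cost = np.abs(A[:, :, None] - B[:, None, :])
    return _dtw_batch(cost)


def pair_distance_matrix(
    gi: GeneTrajectoryMatrix, gj: GeneTrajectoryMatrix
) -> PairDistanceMatrix:
    """The N x N cross-subject DTW distance matrix for one gene pair.

    Trajectories are z-scored here; z-scoring is idempotent, so feeding
    already-normalized trajectories changes nothing.
    """
    if gi.values.shape != gj.values.shape:
        raise ValueError("gene trajectory matrices must share N and T")
    zi = zscore_rows(gi.values)
    zj = zscore_rows(gj.values)
    return PairDistanceMatrix(dtw_pairwise(zi, zj), (gi.gene_id, gj.gene_id))


def redundancy(D: PairDistanceMatrix | np.ndarray, variant: str = "C") -> float:
    """Reduce a distance matrix to a scalar redundancy.

    ``C``: 1 / mean of all N^2 entries.  ``M``: 1 / mean of the N diagonal
    entries.  The mean is floored at EPS so duplicate genes give a large
    finite value.
    """
    d = D.D if isinstance(D, PairDistanceMatrix) else np.asarray(D, dtype=float)
    if variant == "C":
        mean_d = d.mean()
    elif variant == "M":
        mean_d = np.diagonal(d).mean()
    else:
        raise ValueError(f"unknown redundancy variant {variant!r}")
    return float(1.0 / max(mean_d, EPS))


def pair_redundancy(
    gi: GeneTrajectoryMatrix, gj: GeneTrajectoryMatrix, variant: str = "C"
) -> float:
    """Redundancy of a gene pair, computing only the distances the variant needs."""
    if variant == "M":
        zi = zscore_rows(gi.values)
        zj = zscore_rows(gj.values)
        return float(1.0 / max(dtw_paired(zi, zj).mean(), EPS))
    return redundancy(pair_distance_matrix(gi, gj), variant)


@dataclass
class RedundancyCache:
    """Memoized pairwise redundancies over a z-scored gene pool.

    The greedy selection loop revisits the same gene pairs at every step;
    entries are computed on first use and reused after.  Counters record the
    number of distinct redundancy evaluations and of DTW cell computations
    (one 'call' = one trajectory-vs-trajectory dynamic program), which the
    complexity checks consume.
    """

    ztrajs: np.ndarray  # (G_pool, N, T), rows already z-scored
    variant: str = "C"
    n_redundancy_evals: int = 0
    n_dtw_calls: int = 0
    _store: dict[tuple[int, int], float] = field(default_factory=dict)

    def value(self, i: int, j: int) -> float:
        key = (i, j) if i <= j else (j, i)
        hit = self._store.get(key)
        if hit is not None:
            return hit
        zi, zj = self.ztrajs[key[0]], self.ztrajs[key[1]]
        n = zi.shape[0]
        if self.variant == "M":
            mean_d = dtw_paired(zi, zj).mean()
            self.n_dtw_calls += n
        else:
            mean_d = dtw_pairwise(zi, zj).mean()
            self.n_dtw_calls += n * n
        r = float(1.0 / max(mean_d, EPS))
        self._store[key] = r
        self.n_redundancy_evals += 1
        return r


def pool_redundancy_matrix(
    pool: list[GeneTrajectoryMatrix], variant: str = "C"
) -> RedundancyMatrix:
    """Full symmetric redundancy matrix over a candidate pool (eager)."""
    if not pool:
        raise ValueError("empty pool")
    ztrajs = np.stack([zscore_rows(g.values) for g in pool])
    cache = RedundancyCache(ztrajs, variant)
    g = len(pool)
    R = np.empty((g, g))
    for i in range(g):
        for j in range(i, g):
            R[i, j] = R[j, i] = cache.value(i, j)
    return RedundancyMatrix(R, tuple(g.gene_id for g in pool), variant)
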