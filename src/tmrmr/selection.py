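"""Greedy minimum-redundancy maximum-relevance selection.

The temporal variants (TMRMR-C / TMRMR-M) restrict candidates to the
alpha-pool — the top ``round(alpha * G)`` genes by aggregate relevance —
seed the selected set S with the single most relevant gene, and then grow S
one gene at a time, each step adding the candidate g_k maximizing the MIQ
quotient

    V_F / W_dtw,   V_F = mean relevance over S u {g_k},
                   W_dtw = mean pairwise redundancy over S u {g_k}.

W averages the off-diagonal ordered pairs only and is defined as 1 for a
singleton, so the seeding step reduces to pure maximum relevance.  (Under the
matched-subject redundancy a gene's self-redundancy is 1/0 — a trajectory is
at DTW distance 0 from itself — so the literal i = j terms of the double sum
are excluded throughout; this is the one deliberate deviation from the
printed double sum and is documented in the methods note.)

The classical baseline runs the same greedy engine on the flattened
N x (G*T) matrix with per-column F relevance and absolute Pearson
correlation redundancy, under MIQ (default) or MID.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import FlattenedDataset, TemporalDataset
from .redundancy import EPS, RedundancyCache, zscore_rows
from .relevance import f_statistics_tensor, rank_by_relevance, relevance_all

__all__ = [
    "SelectionConfig",
    "RankedGeneList",
    "ConfigError",
    "pool_size",
    "objective",
    "select_tmrmr",
    "select_mrmr_flat",
    "select",
    "write_ranked_list",
]

logger = logging.getLogger(__name__)

VARIANTS = ("TMRMR_C", "TMRMR_M", "MRMR_FLAT")


class ConfigError(ValueError):
    """Invalid selection configuration (alpha range, m vs pool size, variant)."""


@dataclass(frozen=True)
class SelectionConfig:
    """Configuration of one selection run.

    alpha restricts the candidate pool to the top ``round(alpha*G)`` genes by
    aggregate relevance (default 0.3); m is the number of genes to select;
    criterion MID (relevance minus redundancy) applies to the flat baseline
    only — the temporal variants are quotient-form by construction.
    """

    variant: str = "TMRMR_C"
    alpha: float = 0.3
    m: int = 10
    aggregator: str = "mean"
    criterion: str = "MIQ"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.m < 1:
            raise ConfigError(f"m must be positive, got {self.m}")
        if self.criterion not in ("MIQ", "MID"):
            raise ConfigError(f"criterion must be MIQ or MID, got {self.criterion!r}")
        if self.criterion == "MID" and self.variant != "MRMR_FLAT":
            raise ConfigError("MID is available for the flat baseline only")


@dataclass(frozen=True)
class RankedGeneList:
    """Ordered selection result: one row per greedy step."""

    gene_ids: tuple[str, ...]
    gene_indices: tuple[int, ...]
    objective_trace: tuple[float, ...]
    relevances: tuple[float, ...]
    variant: str
    # bookkeeping for complexity checks; 0 for the flat baseline
    n_redundancy_evals: int = 0
    n_dtw_calls: int = 0

    def __len__(self) -> int:
        return len(self.gene_ids)


def pool_size(alpha: float, G: int) -> int:
    """Number of candidate genes: round(alpha*G), half away from zero, in [1, G]."""
    if not (0.0 < alpha <= 1.0):
        raise ConfigError(f"alpha must lie in (0, 1], got {alpha}")
    if G < 1:
        raise ConfigError(f"G must be >= 1, got {G}")
    size = int(np.floor(alpha * G + 0.5))
    return max(1, min(size, G))


def objective(S_relevances: np.ndarray, S_redundancies: np.ndarray) -> float:
    """MIQ quotient V/W for a candidate set.

    V is the mean relevance; W the mean off-diagonal redundancy over ordered
    pairs (1 for a singleton).  W is floored at EPS so duplicate-free sets
    with vanishing redundancy stay finite and ordered.
    """
    rel = np.asarray(S_relevances, dtype=float)
    s = rel.size
    if s < 1:
        raise ValueError("need at least one selected gene")
    v = rel.mean()
    if s == 1:
        w = 1.0
    else:
        R = np.asarray(S_redundancies, dtype=float)
        w = (R.sum() - np.trace(R)) / (s * (s - 1))
    return float(v / max(w, EPS))


def _finite_relevances(rel_pool: np.ndarray) -> np.ndarray:
    """Replace inf sentinels by 10x the largest finite pool relevance."""
    rel = np.asarray(rel_pool, dtype=float).copy()
    inf = np.isinf(rel)
    if inf.any():
        finite = rel[~inf]
        cap = 10.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
        rel[inf] = cap
        warnings.warn(
            f"{inf.sum()} gene(s) with infinite relevance capped at {cap:g} "
            "inside the selection objective",
            RuntimeWarning,
            stacklevel=3,
        )
    return rel


def _greedy(
    rel: np.ndarray,
    red_fn,
    order: np.ndarray,
    m: int,
    criterion: str,
) -> tuple[list[int], list[float]]:
    """Greedy MIQ/MID loop over candidate indices in ``order``.

    ``rel`` holds (finite) relevances indexed like ``order`` members;
    ``red_fn(i, j)`` returns the pairwise redundancy.  Seeds with the first
    element of ``order`` (the most relevant candidate); ties at each step
    break toward the smaller gene index.  Incremental sums keep each step
    O(pool): for S of size s with pairwise sum P = sum_{i<j in S} R[i,j],
    adding k gives W = 2 (P + sum_{i in S} R[i,k]) / (s(s+1)).
    """
    selected = [int(order[0])]
    trace = [rel[selected[0]] if criterion == "MIQ" else rel[selected[0]]]
    logger.debug("step 1: seed gene %d (relevance %.6g)", selected[0], trace[0])
    remaining = [int(g) for g in order[1:]]
    rel_sum = rel[selected[0]]
    pair_sum = 0.0  # sum over unordered selected pairs
    cross = {g: 0.0 for g in remaining}  # sum_{i in S} R[i, g]
    while len(selected) < m and remaining:
        s_new = len(selected) + 1
        last = selected[-1]
        for g in remaining:
            cross[g] += red_fn(last, g)
        best_g, best_obj = None, -np.inf
        for g in remaining:  # ascending gene index order -> first max wins ties
            v = (rel_sum + rel[g]) / s_new
            w = 2.0 * (pair_sum + cross[g]) / (s_new * (s_new - 1))
            obj = v / max(w, EPS) if criterion == "MIQ" else v - w
            if obj > best_obj:
                best_g, best_obj = g, obj
        assert best_g is not None
        logger.debug(
            "step %d: gene %d objective %.6g", s_new, best_g, best_obj
        )
        selected.append(best_g)
        trace.append(best_obj)
        rel_sum += rel[best_g]
        pair_sum += cross.pop(best_g)
        remaining.remove(best_g)
    return selected, [float(x) for x in trace]


def select_tmrmr(ds: TemporalDataset, cfg: SelectionConfig) -> RankedGeneList:
    """Run TMRMR-C or TMRMR-M on a preprocessed temporal dataset.

    Steps: aggregate relevance for all G genes; restrict to the alpha-pool;
    seed with the top-relevance gene; grow greedily under the MIQ quotient
    with the chosen redundancy variant.
    """
    if cfg.variant not in ("TMRMR_C", "TMRMR_M"):
        raise ConfigError(f"select_tmrmr handles temporal variants, got {cfg.variant}")
    if ds.has_missing():
        raise ValueError("dataset has missing values; run impute_linear first")
    _, agg = relevance_all(ds, cfg.aggregator)
    ranked = rank_by_relevance(agg)
    psize = pool_size(cfg.alpha, ds.n_genes)
    if cfg.m > psize:
        raise ConfigError(f"m={cfg.m} exceeds pool size {psize}")
    pool = np.sort(ranked[:psize])  # pool indexed by ascending gene index
    rel_pool = _finite_relevances(agg[pool])
    ztrajs = np.stack([zscore_rows(ds.expression[:, j, :]) for j in pool])
    cache = RedundancyCache(ztrajs, "M" if cfg.variant == "TMRMR_M" else "C")
    # candidate order: most relevant first for seeding, then ascending index
    seed_local = int(np.argwhere(pool == ranked[0])[0, 0])
    order = np.concatenate(([seed_local], np.delete(np.arange(psize), seed_local)))
    sel_local, trace = _greedy(rel_pool, cache.value, order, cfg.m, "MIQ")
    sel = [int(pool[i]) for i in sel_local]
    return RankedGeneList(
        gene_ids=tuple(ds.gene_ids[j] for j in sel),
        gene_indices=tuple(sel),
        objective_trace=tuple(trace),
        relevances=tuple(float(agg[j]) for j in sel),
        variant=cfg.variant,
        n_redundancy_evals=cache.n_redundancy_evals,
        n_dtw_calls=cache.n_dtw_calls,
    )


class _PearsonCache:
    """Lazy |Pearson| redundancy between flattened columns; constant columns
    correlate 0 with everything by convention."""

    def __init__(self, matrix: np.ndarray) -> None:
        x = np.asarray(matrix, dtype=float)
        centered = x - x.mean(axis=0)
        norms = np.linalg.norm(centered, axis=0)
        self._cols = centered
        self._norms = norms
        self._store: dict[tuple[int, int], float] = {}

    def value(self, i: int, j: int) -> float:
        key = (i, j) if i <= j else (j, i)
        hit = self._store.get(key)
        if hit is None:
            ni, nj = self._norms[key[0]], self._norms[key[1]]
            if ni == 0 or nj == 0:
                hit = 0.0
            else:
                hit = abs(float(self._cols[:, key[0]] @ self._cols[:, key[1]]) / (ni * nj))
            self._store[key] = hit
        return hit


def select_mrmr_flat(flat: FlattenedDataset, cfg: SelectionConfig) -> RankedGeneList:
    """Classical mRMR on the flattened matrix (column features).

    Relevance is the per-column one-way F; redundancy the absolute Pearson
    correlation between columns; criterion MIQ or MID.  ``cfg.m`` counts
    selected *columns*; the distinct parent genes in first-selection order
    are recoverable from the returned column ids.
    """
    if cfg.variant != "MRMR_FLAT":
        raise ConfigError(f"select_mrmr_flat requires variant MRMR_FLAT, got {cfg.variant}")
    x = flat.matrix
    n_cols = x.shape[1]
    f = f_statistics_tensor(x[:, :, None], flat.labels)[:, 0]
    ranked = rank_by_relevance(f)
    psize = pool_size(cfg.alpha, n_cols)
    if cfg.m > psize:
        raise ConfigError(f"m={cfg.m} exceeds pool size {psize}")
    pool = np.sort(ranked[:psize])
    rel_pool = _finite_relevances(f[pool])
    cache = _PearsonCache(x[:, pool])
    seed_local = int(np.argwhere(pool == ranked[0])[0, 0])
    order = np.concatenate(([seed_local], np.delete(np.arange(pool.size), seed_local)))
    sel_local, trace = _greedy(rel_pool, cache.value, order, cfg.m, cfg.criterion)
    sel = [int(pool[i]) for i in sel_local]
    ids = tuple(f"{flat.column_ids[j][0]}@t{flat.column_ids[j][1]:g}" for j in sel)
    return RankedGeneList(
        gene_ids=ids,
        gene_indices=tuple(sel),
        objective_trace=tuple(trace),
        relevances=tuple(float(f[j]) for j in sel),
        variant="MRMR_FLAT",
    )


def select(ds: TemporalDataset, cfg: SelectionConfig) -> RankedGeneList:
    """Dispatch on variant: temporal TMRMR or the flattened baseline."""
    if cfg.variant == "MRMR_FLAT":
        from .dataset import flatten

        return select_mrmr_flat(flatten(ds), cfg)
    return select_tmrmr(ds, cfg)


def write_ranked_list(result: RankedGeneList, path: str | Path) -> None:
    """Write the selection as delimited text: rank, gene_id, objective, relevance."""
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(result) + 1),
            "gene_id": result.gene_ids,
            "objective_at_selection": result.objective_trace,
            "aggregate_F": result.relevances,
        }
    )
    df.to_csv(path, index=False)
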