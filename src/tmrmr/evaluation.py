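"""Cross-validated evaluation harness and selection-stability metrics.

Feature selection happens strictly inside each training fold: per-gene
min-max normalization is refit on training subjects (test values clipped to
[0, 1]), genes are selected on training subjects only, and the classifier —
anything exposing ``fit(X, y)`` / ``predict(X)`` — consumes the selected
genes' flattened trajectories per subject (an m*T vector).

Stability across folds is summarized by the count of genes shared by all
folds, the mean Tanimoto similarity (intersection over union) over fold
pairs, and the mean Spearman rank correlation over fold pairs, computed on
the union of each pair's lists with absent genes placed at tied rank m+1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.model_selection import StratifiedKFold

from .dataset import TemporalDataset, gene_bounds, impute_linear, minmax_normalize
from .selection import RankedGeneList, SelectionConfig, select

__all__ = [
    "FoldPlan",
    "StabilityReport",
    "make_folds",
    "evenly_spaced_times",
    "run_cv",
    "stability",
]


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition of subjects into folds."""

    n_folds: int
    assignments: np.ndarray  # fold id per subject, 0..n_folds-1
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass(frozen=True)
class StabilityReport:
    """Cross-fold agreement of top-m gene lists."""

    n_shared: int
    spearman_rho: float
    tanimoto: float
    m: int


def make_folds(ds: TemporalDataset, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Reproducible stratified k-fold assignment of subjects."""
    if n_folds > ds.n_subjects:
        raise ValueError(f"n_folds={n_folds} exceeds N={ds.n_subjects}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(ds.n_subjects, dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros(ds.n_subjects), ds.labels)):
        assignments[test] = fold
    return FoldPlan(n_folds, assignments, seed)


def evenly_spaced_times(T: int, count: int) -> np.ndarray:
    """First, last and equally distant interior time positions (0-based)."""
    if count < 2 or count > T:
        raise ValueError(f"count must lie in [2, T={T}]")
    return np.unique(np.round(np.linspace(0, T - 1, count)).astype(int))


def _feature_matrix(ds: TemporalDataset, gene_indices: Sequence[int]) -> np.ndarray:
    """Per-subject feature vectors: selected genes' trajectories, flattened."""
    sub = ds.expression[:, list(gene_indices), :]
    return sub.reshape(ds.n_subjects, -1)


def run_cv(
    ds: TemporalDataset,
    cfg: SelectionConfig,
    m_grid: Sequence[int],
    classifier_factory,
    folds: FoldPlan,
    time_subset: int | Sequence[int] | None = None,
) -> tuple[pd.DataFrame, list[RankedGeneList]]:
    """Cross-validated accuracy of a selection method + classifier.

    ``classifier_factory()`` must return a fresh object with ``fit``/
    ``predict`` per fold.  ``time_subset`` restricts T before everything:
    an int keeps that many evenly spaced time points (always including the
    first and last); a sequence is used as explicit 0-based time positions.
    Genes are selected once per fold at max(m_grid); smaller m values use
    prefixes of that ranking (the greedy selection order is prefix-stable).

    Returns the accuracy table (method, variant, m, fold, accuracy, n_test)
    plus one RankedGeneList per fold, and appends a pooled per-subject row
    (fold = -1) per m.
    """
    if time_subset is not None:
        idx = (
            evenly_spaced_times(ds.n_times, time_subset)
            if isinstance(time_subset, (int, np.integer))
            else np.asarray(list(time_subset), dtype=int)
        )
        ds = ds.subset_times(idx)
    ds = impute_linear(ds)
    m_grid = sorted(int(m) for m in m_grid)
    m_max = m_grid[-1]
    cfg_run = SelectionConfig(
        variant=cfg.variant,
        alpha=cfg.alpha,
        m=m_max,
        aggregator=cfg.aggregator,
        criterion=cfg.criterion,
    )
    rows = []
    fold_lists: list[RankedGeneList] = []
    pooled: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {m: [] for m in m_grid}
    for fold in range(folds.n_folds):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        train = ds.subset_subjects(tr)
        test = ds.subset_subjects(te)
        bounds = gene_bounds(train)
        train = minmax_normalize(train)
        test = minmax_normalize(test, bounds=bounds)  # train-fitted, clipped
        result = select(train, cfg_run)
        fold_lists.append(result)
        if cfg.variant == "MRMR_FLAT":
            # column features: map selected flat columns back to parent genes
            gidx = _flat_parent_genes(result, train)
        else:
            gidx = list(result.gene_indices)
        for m in m_grid:
            sel = gidx[:m] if len(gidx) >= m else gidx
            clf = classifier_factory()
            clf.fit(_feature_matrix(train, sel), train.labels)
            pred = np.asarray(clf.predict(_feature_matrix(test, sel)))
            acc = float((pred == test.labels).mean())
            rows.append(
                {
                    "variant": cfg.variant,
                    "m": m,
                    "fold": fold,
                    "accuracy": acc,
                    "n_test": te.size,
                }
            )
            pooled[m].append((pred, test.labels))
    for m in m_grid:
        preds = np.concatenate([p for p, _ in pooled[m]])
        labs = np.concatenate([l for _, l in pooled[m]])
        rows.append(
            {
                "variant": cfg.variant,
                "m": m,
                "fold": -1,  # pooled per-subject accuracy over all folds
                "accuracy": float((preds == labs).mean()),
                "n_test": labs.size,
            }
        )
    return pd.DataFrame(rows), fold_lists


def _flat_parent_genes(result: RankedGeneList, ds: TemporalDataset) -> list[int]:
    """Distinct parent gene indices of selected flat columns, in first-selection order."""
    seen: list[int] = []
    for col in result.gene_indices:
        parent = col // ds.n_times
        if parent not in seen:
            seen.append(parent)
    return seen


def _pair_spearman(a: Sequence[str], b: Sequence[str], m: int) -> float:
    """Spearman rho on the union of two top-m lists, absent genes at tied rank m+1."""
    union = sorted(set(a) | set(b))
    rank_a = {g: i + 1 for i, g in enumerate(a)}
    rank_b = {g: i + 1 for i, g in enumerate(b)}
    ra = [rank_a.get(g, m + 1) for g in union]
    rb = [rank_b.get(g, m + 1) for g in union]
    rho = spearmanr(ra, rb).statistic
    return float(rho) if np.isfinite(rho) else 1.0  # identical constant ranks


def stability(fold_lists: Sequence[RankedGeneList | Sequence[str]]) -> StabilityReport:
    """Cross-fold stability of selected gene lists (all lists same length m)."""
    lists = [
        list(fl.gene_ids) if isinstance(fl, RankedGeneList) else list(fl)
        for fl in fold_lists
    ]
    lengths = {len(l) for l in lists}
    if len(lengths) != 1:
        raise ValueError(f"fold lists differ in length: {sorted(lengths)}")
    m = lengths.pop()
    sets = [set(l) for l in lists]
    shared = set.intersection(*sets) if sets else set()
    tanimotos, rhos = [], []
    for (la, sa), (lb, sb) in combinations(zip(lists, sets), 2):
        tanimotos.append(len(sa & sb) / len(sa | sb))
        rhos.append(_pair_spearman(la, lb, m))
    return StabilityReport(
        n_shared=len(shared),
        spearman_rho=float(np.mean(rhos)) if rhos else 1.0,
        tanimoto=float(np.mean(tanimotos)) if tanimotos else 1.0,
        m=m,
    )
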