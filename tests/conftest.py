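"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (exhaustive path
enumeration, textbook sum-of-squares ANOVA, from-scratch greedy re-evaluation)
kept free of the vectorized code paths they validate.
"""

from __future__ import annotations

import numpy as np
import pytest

import tmrmr


# ---------------------------------------------------------------------------
# oracles


def brute_force_dtw(a, b) -> float:
    """Minimum cost over an exhaustive enumeration of all monotone
    boundary-matched warping paths with steps (1,0), (0,1), (1,1)."""
    a = list(map(float, a))
    b = list(map(float, b))
    la, lb = len(a), len(b)
    best = [np.inf]

    def rec(u: int, v: int, acc: float) -> None:
        acc = acc + abs(a[u] - b[v])
        if acc >= best[0]:
            return  # no negative costs: safe to prune
        if u == la - 1 and v == lb - 1:
            best[0] = acc
            return
        if u + 1 < la:
            rec(u + 1, v, acc)
        if v + 1 < lb:
            rec(u, v + 1, acc)
        if u + 1 < la and v + 1 < lb:
            rec(u + 1, v + 1, acc)

    rec(0, 0, 0.0)
    return float(best[0])


def anova_f_by_decomposition(values, labels) -> float:
    """One-way F via an explicit per-class sum-of-squares decomposition."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = sorted(set(labels.tolist()))
    n, k = values.size, len(classes)
    grand = values.mean()
    ssb = ssw = 0.0
    for c in classes:
        grp = values[labels == c]
        ssb += grp.size * (grp.mean() - grand) ** 2
        ssw += ((grp - grp.mean()) ** 2).sum()
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def naive_objective(relevances, redundancy_lookup, members) -> float:
    """V/W for a candidate set, recomputed from scratch by double loops."""
    members = list(members)
    s = len(members)
    v = sum(relevances[g] for g in members) / s
    if s == 1:
        w = 1.0
    else:
        total = 0.0
        for gi in members:
            for gj in members:
                if gi != gj:
                    total += redundancy_lookup(gi, gj)
        w = total / (s * (s - 1))
    return v / max(w, 1e-12)


def naive_greedy_trace(relevances, redundancy_lookup, pool, m):
    """Independent greedy MIQ: full re-evaluation of every candidate at every
    step, seeding with the most relevant pool gene, ties by ascending index."""
    pool = sorted(pool)
    seed = max(pool, key=lambda g: (relevances[g], -g))
    selected = [seed]
    while len(selected) < m:
        best_g, best_obj = None, -np.inf
        for g in pool:
            if g in selected:
                continue
            obj = naive_objective(relevances, redundancy_lookup, selected + [g])
            if obj > best_obj:
                best_g, best_obj = g, obj
        selected.append(best_g)
    return selected


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def worked():
    return tmrmr.worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dataset(rng, n=6, g=8, t=5, k=2):
    """Unstructured random dataset; labels interleaved so classes balance."""
    labels = np.array([(p % k) + 1 for p in range(n)])
    return tmrmr.TemporalDataset(
        expression=rng.normal(size=(n, g, t)),
        labels=labels,
        gene_ids=tuple(f"g{j}" for j in range(g)),
        subject_ids=tuple(f"s{p}" for p in range(n)),
        time_index=np.arange(t, dtype=float),
    )
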