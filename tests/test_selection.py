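"""Greedy MIQ selection: pool restriction, objective, step-optimality."""

import numpy as np
import pytest

from conftest import naive_greedy_trace, naive_objective, random_dataset
from tmrmr.dataset import flatten
from tmrmr.redundancy import pair_redundancy
from tmrmr.relevance import relevance_all
from tmrmr.selection import (
    ConfigError,
    SelectionConfig,
    objective,
    pool_size,
    select_mrmr_flat,
    select_tmrmr,
)


class TestPoolSize:
    @pytest.mark.parametrize(
        "alpha,G,expected",
        [(1.0, 50, 50), (0.5, 10, 5), (0.3, 12023, 3607), (0.3, 1, 1), (0.01, 10, 1)],
    )
    def test_round_half_away_clamped(self, alpha, G, expected):
        assert pool_size(alpha, G) == expected

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            pool_size(0.0, 10)
        with pytest.raises(ConfigError):
            pool_size(1.5, 10)


class TestObjective:
    def test_singleton_convention(self):
        assert objective(np.array([4.2]), np.array([[1e12]])) == pytest.approx(4.2)

    def test_pair_arithmetic(self):
        R = np.array([[9.0, 0.5], [0.5, 9.0]])
        assert objective(np.array([2.0, 2.0]), R) == pytest.approx(4.0)

    def test_matches_naive_double_loop(self, rng):
        rel = rng.uniform(1, 10, size=4)
        R = rng.uniform(0.1, 1.0, size=(4, 4))
        R = (R + R.T) / 2
        lookup = lambda i, j: R[i, j]
        expected = naive_objective(dict(enumerate(rel)), lookup, range(4))
        assert objective(rel, R) == pytest.approx(expected, rel=1e-12)


def _redundancy_lookup(ds, variant):
    cache = {}

    def lookup(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = pair_redundancy(ds.gene(key[0]), ds.gene(key[1]), variant)
        return cache[key]

    return lookup


class TestTmrmrSelection:
    def test_m1_returns_top_relevance_gene(self, rng):
        ds = random_dataset(rng, n=6, g=8, t=4)
        _, agg = relevance_all(ds)
        res = select_tmrmr(ds, SelectionConfig(variant="TMRMR_C", alpha=1.0, m=1))
        assert res.gene_indices[0] == int(np.argmax(agg))

    @pytest.mark.parametrize("variant", ["TMRMR_C", "TMRMR_M"])
    def test_greedy_matches_naive_reevaluation(self, variant, rng):
        # every step's winner recomputed from scratch by the independent oracle
        for trial in range(6):
            ds = random_dataset(rng, n=4, g=8, t=4)
            _, agg = relevance_all(ds)
            res = select_tmrmr(ds, SelectionConfig(variant=variant, alpha=1.0, m=4))
            lookup = _redundancy_lookup(ds, "M" if variant == "TMRMR_M" else "C")
            expected = naive_greedy_trace(dict(enumerate(agg)), lookup, range(8), 4)
            assert list(res.gene_indices) == expected

    @pytest.mark.parametrize("variant", ["TMRMR_C", "TMRMR_M"])
    def test_prefix_property(self, variant, rng):
        ds = random_dataset(rng, n=5, g=10, t=4)
        short = select_tmrmr(ds, SelectionConfig(variant=variant, alpha=0.8, m=3))
        longer = select_tmrmr(ds, SelectionConfig(variant=variant, alpha=0.8, m=4))
        assert longer.gene_indices[:3] == short.gene_indices

    def test_selection_confined_to_alpha_pool_and_pool_matters(self, rng):
        ds = random_dataset(rng, n=5, g=10, t=4)
        _, agg = relevance_all(ds)
        pool = set(np.argsort(-agg, kind="stable")[: pool_size(0.4, 10)])
        res = select_tmrmr(ds, SelectionConfig(variant="TMRMR_C", alpha=0.4, m=3))
        assert set(res.gene_indices) <= pool
        full = select_tmrmr(ds, SelectionConfig(variant="TMRMR_C", alpha=1.0, m=3))
        if set(full.gene_indices) - pool:
            assert res.gene_indices != full.gene_indices

    def test_equal_redundancy_reduces_to_relevance_order(self, monkeypatch, rng):
        import tmrmr.selection as sel

        ds = random_dataset(rng, n=5, g=6, t=4)
        _, agg = relevance_all(ds)

        class FlatCache:
            n_redundancy_evals = 0
            n_dtw_calls = 0

            def __init__(self, *a, **k):
                pass

            def value(self, i, j):
                return 0.37

        monkeypatch.setattr(sel, "RedundancyCache", FlatCache)
        res = select_tmrmr(ds, SelectionConfig(variant="TMRMR_C", alpha=1.0, m=4))
        expected = list(np.lexsort((np.arange(6), -agg))[:4])
        assert list(res.gene_indices) == expected

    def test_m_exceeding_pool_rejected(self, rng):
        ds = random_dataset(rng, n=4, g=6, t=3)
        with pytest.raises(ConfigError):
            select_tmrmr(ds, SelectionConfig(variant="TMRMR_C", alpha=0.5, m=5))

    def test_duplicate_gene_not_selected_consecutively(self, rng):
        # near-duplicate of the top gene: TMRMR-M must not take it second
        ds = random_dataset(rng, n=6, g=6, t=5)
        expr = ds.expression.copy()
        signal = np.linspace(0, 1, 5)
        expr[:, 0, :] = np.where(ds.labels == 1, 1.0, -1.0)[:, None] * signal + 0.05 * expr[:, 0, :]
        expr[:, 1, :] = expr[:, 0, :] * 2.3 + 0.7  # affine copy: identical shape
        from dataclasses import replace

        ds = replace(ds, expression=expr)
        res = select_tmrmr(ds, SelectionConfig(variant="TMRMR_M", alpha=1.0, m=3))
        assert res.gene_indices[0] in (0, 1)
        assert set(res.gene_indices[:2]) != {0, 1}

    def test_complexity_counters_within_bound(self, rng):
        ds = random_dataset(rng, n=5, g=12, t=4)
        cfg = SelectionConfig(variant="TMRMR_C", alpha=0.5, m=4)
        res = select_tmrmr(ds, cfg)
        psize = pool_size(0.5, 12)
        assert res.n_redundancy_evals <= psize * 4
        resm = select_tmrmr(ds, SelectionConfig(variant="TMRMR_M", alpha=0.5, m=4))
        # matched variant: O(N) DTW calls per pair vs O(N^2) for full variant
        assert resm.n_dtw_calls == resm.n_redundancy_evals * 5
        assert res.n_dtw_calls == res.n_redundancy_evals * 25


class TestFlatBaseline:
    def test_single_column_m1(self, rng):
        ds = random_dataset(rng, n=6, g=1, t=1)
        flat = flatten(ds)
        res = select_mrmr_flat(flat, SelectionConfig(variant="MRMR_FLAT", alpha=1.0, m=1))
        assert res.gene_indices == (0,)

    def test_duplicate_column_not_taken_second(self, rng):
        ds = random_dataset(rng, n=8, g=3, t=2)
        expr = ds.expression.copy()
        signal = np.where(ds.labels == 1, 1.0, 0.0)
        expr[:, 0, 0] = signal + 0.01 * rng.normal(size=8)
        expr[:, 0, 1] = expr[:, 0, 0]  # identical duplicate of the top column
        from dataclasses import replace

        flat = flatten(replace(ds, expression=expr))
        res = select_mrmr_flat(flat, SelectionConfig(variant="MRMR_FLAT", alpha=1.0, m=2))
        assert res.gene_indices[0] == 0
        assert res.gene_indices[1] != 1

    @pytest.mark.parametrize("criterion", ["MIQ", "MID"])
    def test_each_step_matches_exhaustive_argmax(self, criterion, rng):
        ds = random_dataset(rng, n=6, g=3, t=2)
        flat = flatten(ds)
        res = select_mrmr_flat(
            flat, SelectionConfig(variant="MRMR_FLAT", alpha=1.0, m=3, criterion=criterion)
        )
        from tmrmr.relevance import f_statistics_tensor

        f = f_statistics_tensor(flat.matrix[:, :, None], flat.labels)[:, 0]
        corr = np.abs(np.corrcoef(flat.matrix.T))

        def obj(members):
            v = np.mean([f[g] for g in members])
            if len(members) == 1:
                return v
            w = np.mean([corr[i, j] for i in members for j in members if i != j])
            return v / max(w, 1e-12) if criterion == "MIQ" else v - w

        selected = [int(np.argmax(f))]
        while len(selected) < 3:
            cands = [g for g in range(6) if g not in selected]
            best = max(cands, key=lambda g: (obj(selected + [g]), -g))
            selected.append(best)
        assert list(res.gene_indices) == selected

    def test_mid_restricted_to_baseline(self):
        with pytest.raises(ConfigError):
            SelectionConfig(variant="TMRMR_C", criterion="MID")
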