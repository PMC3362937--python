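"""Tabulation-based exact conflict-region solver."""

import itertools
import math

import numpy as np
import pytest

from consmap.conflicts import ConflictRegion, delineate_regions, detect_conflicts
from consmap.exceptions import FeasibilityError
from consmap.local_exact import (
    build_insertion_tables,
    estimate_complexity,
    solve_region,
)

from .conftest import (
    arbitrary_rf_named,
    make_map,
    path_cost,
    random_region_instance,
    region_bruteforce,
)


def _mk_region(k, n_by, flanks=("L", "R")):
    shared = [f"s{j + 1}" for j in range(k)]
    windows = {i: (1, k + n) for i, n in n_by.items()}
    uniques = {i: [f"u{i}_{j + 1}" for j in range(n)] for i, n in n_by.items()}
    return ConflictRegion(shared, windows, uniques, {i: flanks for i in n_by})


class TestComplexity:
    def test_printed_formula_values(self):
        """k=4, n=10: 1024 * 14 = 14336 stage-1 entries and
        24 * 5^10 = 234,375,000 stage-2 combinations."""
        region = _mk_region(4, {0: 10})
        est = estimate_complexity(region)
        assert est.stage1_entries[0] == 14336
        assert est.stage2_combinations == 234_375_000
        assert est.feasible  # k + n = 14 < 15, k = 4 < 11, n = 10 < 11

    def test_feasibility_bound(self):
        assert estimate_complexity(_mk_region(4, {0: 10})).feasible
        assert not estimate_complexity(_mk_region(4, {0: 11})).feasible
        assert not estimate_complexity(_mk_region(11, {0: 1})).feasible
        assert not estimate_complexity(_mk_region(7, {0: 8})).feasible

    def test_no_uniques_is_factorial(self):
        est = estimate_complexity(_mk_region(5, {0: 0, 1: 0}))
        assert est.stage2_combinations == math.factorial(5)

    @pytest.mark.parametrize("k,n", [(2, 2), (3, 1), (3, 3), (5, 2)])
    def test_formulas_match_direct_counting(self, k, n):
        """Stage counts equal explicit enumeration of the table keys and
        of the candidate-order space."""
        est = estimate_complexity(_mk_region(k, {0: n}))
        anchors = list(range(k + 2))
        pairs = [
            p
            for p in itertools.combinations(anchors, 2)
            if p != (0, k + 1)  # the flank-flank pair is excluded
        ]
        subsets = list(
            itertools.chain.from_iterable(
                itertools.combinations(range(n), r) for r in range(n + 1)
            )
        )
        assert est.stage1_entries[0] == len(pairs) * len(subsets)
        n_orders = len(list(itertools.permutations(range(k))))
        n_assignments = len(list(itertools.product(range(k + 1), repeat=n)))
        assert est.stage2_combinations == n_orders * n_assignments


class TestInsertionTable:
    def _table(self, rng, k=2, n=3):
        region, rfs = random_region_instance(rng, n_datasets=1, k=k, n_per=n)
        tables = build_insertion_tables(region, rfs)
        return region, rfs[0], tables[0]

    def test_empty_subset_is_direct_distance(self, rng):
        region, rfm, table = self._table(rng)
        for a, b in itertools.combinations(table.anchors, 2):
            assert table.cost(a, frozenset(), b) == pytest.approx(
                rfm.dist(a, b)
            )

    def test_subset_cost_matches_factorial_oracle(self, rng):
        region, rfm, table = self._table(rng, k=2, n=3)
        T = list(table.uniques)
        for a, b in itertools.combinations(table.anchors, 2):
            oracle = min(
                path_cost([a] + list(p) + [b], rfm)
                for p in itertools.permutations(T)
            )
            assert table.cost(a, frozenset(T), b) == pytest.approx(oracle)
            order = table.order(a, frozenset(T), b)
            assert path_cost([a] + order + [b], rfm) == pytest.approx(oracle)

    def test_cap_raises_feasibility_error(self):
        region = _mk_region(11, {0: 1})
        with pytest.raises(FeasibilityError):
            build_insertion_tables(region, {0: None})


class TestSolveRegion:
    def test_matches_bruteforce_on_random_instances(self):
        for seed in range(30):
            r = np.random.default_rng(5000 + seed)
            nd = int(r.integers(2, 4))
            k = int(r.integers(2, 4))
            n_per = int(r.integers(0, 2))
            region, rfs = random_region_instance(
                r, n_datasets=nd, k=k, n_per=n_per, drop_shared=True
            )
            weights = [1.0] * nd
            tables = build_insertion_tables(region, rfs)
            sol = solve_region(region, tables, weights)
            oracle_total, _ = region_bruteforce(region, rfs, weights)
            assert sol.weighted_total == pytest.approx(oracle_total, abs=1e-9)
            # the returned per-dataset orders achieve the stated costs and
            # embed the winning shared suborder
            for i in region.windows:
                rfm = rfs[i]
                left, right = region.flanks[i]
                full = [left] + sol.per_dataset_orders[i] + [right]
                assert path_cost(full, rfm) == pytest.approx(
                    sol.per_dataset_cost[i]
                )
                proj = [
                    m for m in sol.per_dataset_orders[i]
                    if m in set(region.shared)
                ]
                expect = [
                    m for m in sol.shared_suborder if m in set(rfm.markers)
                ]
                assert proj == expect

    def test_zero_conflict_region_keeps_incumbent(self, rng):
        """When the input suborder is already optimal the solver returns
        it with no length change."""
        markers = ["L", "s1", "s2", "s3", "R"]
        pos = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        from .conftest import map_consistent_rf

        rfm = map_consistent_rf(pos, markers)
        region = ConflictRegion(
            ["s1", "s2", "s3"],
            {0: (1, 3), 1: (1, 3)},
            {0: [], 1: []},
            {0: ("L", "R"), 1: ("L", "R")},
        )
        tables = build_insertion_tables(region, [rfm, rfm])
        sol = solve_region(region, tables, [1.0, 1.0])
        assert sol.shared_suborder == ("s1", "s2", "s3")
        assert sol.per_dataset_cost[0] == pytest.approx(
            path_cost(markers, rfm)
        )

    def test_purity(self, rng):
        region, rfs = random_region_instance(rng, n_datasets=2, k=3, n_per=2)
        weights = [1.0, 1.0]
        tables = build_insertion_tables(region, rfs)
        a = solve_region(region, tables, weights)
        b = solve_region(region, tables, weights)
        assert a.shared_suborder == b.shared_suborder
        assert a.weighted_total == b.weighted_total
        assert a.per_dataset_orders == b.per_dataset_orders

    def test_consensus_cost_never_below_unconstrained(self):
        """Per dataset, the synchronized region length is bounded below by
        that dataset's own unconstrained optimum."""
        for seed in range(10):
            r = np.random.default_rng(7000 + seed)
            region, rfs = random_region_instance(r, n_datasets=3, k=3, n_per=1)
            weights = [1.0] * 3
            tables = build_insertion_tables(region, rfs)
            sol = solve_region(region, tables, weights)
            for i in region.windows:
                rfm = rfs[i]
                content = [
                    m for m in rfm.markers if m not in ("L", "R")
                ]
                unconstrained = min(
                    path_cost(["L"] + list(p) + ["R"], rfm)
                    for p in itertools.permutations(content)
                )
                assert sol.per_dataset_cost[i] >= unconstrained - 1e-9

    def test_free_end_region(self, rng):
        """A region touching the linkage-group end has one free side."""
        region, rfs = random_region_instance(rng, n_datasets=2, k=3, n_per=1)
        for i in region.windows:
            region.flanks[i] = (region.flanks[i][0], None)
            lo, hi = region.windows[i]
            region.windows[i] = (lo, hi)
        # rebuild rf matrices without the right flank
        rfs2 = []
        for rfm in rfs:
            keep = [m for m in rfm.markers if m != "R"]
            idx = [rfm.index(m) for m in keep]
            from consmap.core import RFMatrix

            rfs2.append(
                RFMatrix(
                    keep,
                    rfm.rf[np.ix_(idx, idx)],
                    np.asarray(rfm.n_informative)[np.ix_(idx, idx)],
                )
            )
        tables = build_insertion_tables(region, rfs2)
        sol = solve_region(region, tables, [1.0, 1.0])
        oracle_total, _ = region_bruteforce(region, rfs2, [1.0, 1.0])
        assert sol.weighted_total == pytest.approx(oracle_total, abs=1e-9)
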