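"""Conflict detection, region delineation, pre-correction."""

import itertools

import numpy as np
import pytest

from consmap.conflicts import (
    ConflictPair,
    delineate_regions,
    detect_conflicts,
    orient_maps,
    pre_correct,
    total_conflicts,
)
from consmap.core import align_orientation
from consmap.exceptions import ValidationError
from consmap.simulate import haldane

from .conftest import make_map, map_consistent_rf


def brute_force_conflicts(orders, shared):
    """Independent pair scan with per-pair orientation alignment."""
    found = {}
    for i, j in itertools.combinations(range(len(orders)), 2):
        oi = [m for m in orders[i] if m in shared]
        common = set(oi) & set(orders[j])
        if len(common) < 2:
            continue
        oi_c = [m for m in oi if m in common]
        oj_c = [m for m in orders[j] if m in common]
        # orient j against i by concordance
        pos_i = {m: p for p, m in enumerate(oi_c)}

        def disc(cand):
            pos_j = {m: p for p, m in enumerate(cand)}
            return sum(
                1
                for a, b in itertools.combinations(common, 2)
                if (pos_i[a] - pos_i[b]) * (pos_j[a] - pos_j[b]) < 0
            )

        oj_best = min((oj_c, oj_c[::-1]), key=disc)
        pos_j = {m: p for p, m in enumerate(oj_best)}
        for a, b in itertools.combinations(sorted(common), 2):
            if (pos_i[a] - pos_i[b]) * (pos_j[a] - pos_j[b]) < 0:
                found.setdefault(frozenset((a, b)), set()).update((i, j))
    return found


class TestDetect:
    def test_identical_orders_no_conflict(self):
        maps = [make_map(["a", "b", "c"])] * 3
        assert detect_conflicts(maps, {"a", "b", "c"}) == []

    def test_swapped_pair_detected(self):
        maps = [
            make_map(["x", "a", "b", "y"]),
            make_map(["x", "b", "a", "y"]),
        ]
        out = detect_conflicts(maps, {"x", "a", "b", "y"})
        assert len(out) == 1
        assert out[0].markers == frozenset({"a", "b"})
        assert out[0].dataset_ids == frozenset({0, 1})

    def test_needs_two_maps(self):
        with pytest.raises(ValidationError):
            detect_conflicts([make_map(["a", "b"])], {"a", "b"})

    def test_matches_bruteforce_oracle(self, rng):
        markers = [f"m{i}" for i in range(9)]
        shared = set(markers[:7])
        for _ in range(25):
            orders = []
            for _ in range(4):
                o = list(rng.permutation(markers))
                orders.append(o)
            maps = [make_map(o) for o in orders]
            got = {
                (cp.markers, cp.dataset_ids)
                for cp in detect_conflicts(maps, shared)
            }
            oracle = {
                (frozenset(k), frozenset(v))
                for k, v in brute_force_conflicts(orders, shared).items()
            }
            assert got == oracle

    def test_conflict_pair_validation(self):
        with pytest.raises(ValidationError):
            ConflictPair("a", "a", frozenset({0, 1}))
        with pytest.raises(ValidationError):
            ConflictPair("a", "b", frozenset({0}))


class TestDelineate:
    def test_overlapping_conflicts_merge(self):
        """Chained conflicts (a-b over some sets, b-d extending further)
        collapse into a single region covering both."""
        shared = {"x", "a", "b", "c", "d", "y"}
        true = ["x", "a", "b", "c", "d", "y"]
        swapped_ab = ["x", "b", "a", "c", "d", "y"]
        swapped_bd = ["x", "a", "d", "c", "b", "y"]
        maps = [make_map(true)] * 3 + [make_map(swapped_ab)] * 2 + [
            make_map(swapped_bd)
        ] * 2
        conflicts = detect_conflicts(maps, shared)
        regions = delineate_regions(maps, conflicts, shared)
        assert len(regions) == 1
        assert set(regions[0].shared) >= {"a", "b", "d"}
        # every conflict lies inside the single region
        for cp in conflicts:
            assert cp.markers <= set(regions[0].shared)

    def test_minimal_region_and_flanks(self):
        shared = {"f1", "a", "b", "f2"}
        maps = [
            make_map(["f1", "a", "u1", "b", "f2"]),
            make_map(["f1", "b", "a", "f2"]),
        ]
        conflicts = detect_conflicts(maps, shared)
        regions = delineate_regions(maps, conflicts, shared)
        assert len(regions) == 1
        region = regions[0]
        assert set(region.shared) == {"a", "b"}
        assert region.unique_by_dataset[0] == ["u1"]
        assert region.flanks[0] == ("f1", "f2")
        assert region.flanks[1] == ("f1", "f2")

    def test_disjoint_conflicts_stay_separate(self):
        shared = {"a", "b", "m", "c", "d"}
        maps = [
            make_map(["a", "b", "m", "c", "d"]),
            make_map(["b", "a", "m", "d", "c"]),
        ]
        conflicts = detect_conflicts(maps, shared)
        regions = delineate_regions(maps, conflicts, shared)
        assert len(regions) == 2
        covered = [set(r.shared) for r in regions]
        assert {"a", "b"} in covered and {"c", "d"} in covered
        # markers strictly between regions stay conflict-free
        assert all("m" not in s for s in covered)

    def test_end_of_group_side_is_free(self):
        shared = {"a", "b", "c"}
        maps = [make_map(["a", "b", "c"]), make_map(["b", "a", "c"])]
        conflicts = detect_conflicts(maps, shared)
        regions = delineate_regions(maps, conflicts, shared)
        region = regions[0]
        assert region.flanks[0][0] is None  # reaches the left end
        assert region.flanks[0][1] == "c"

    def test_no_conflicts_no_regions(self):
        maps = [make_map(["a", "b"]), make_map(["a", "b"])]
        assert delineate_regions(maps, [], {"a", "b"}) == []


class TestPreCorrect:
    def _rf_for(self, positions, markers):
        return map_consistent_rf(np.asarray(positions), markers)

    def test_no_gap_no_change(self):
        markers = ["a", "b", "c", "d"]
        rfm = self._rf_for([0, 5, 10, 15], markers)
        maps = [make_map(markers, rfm), make_map(markers, rfm)]
        out, log = pre_correct(maps, [rfm, rfm], set(markers))
        assert log == []
        assert [m.order for m in out] == [markers, markers]

    def test_inversion_beyond_large_gap_corrected(self):
        """A distal segment reversed across a ~0.31 gap conflicts with the
        other map; the inversion move restores a conflict-free order at
        negligible length cost."""
        markers = ["m1", "m2", "m3", "m4", "m5", "m6"]
        pos = [0.0, 5.0, 10.0, 65.0, 70.0, 75.0]  # rf(m3,m4) ~ 0.33
        rfm = self._rf_for(pos, markers)
        assert 0.3 < rfm.dist("m3", "m4") < 0.35
        good = make_map(markers, rfm)
        inverted = make_map(["m1", "m2", "m3", "m6", "m5", "m4"], rfm)
        before = total_conflicts([good, inverted], set(markers))
        assert before > 0
        out, log = pre_correct(
            [good, inverted], [rfm, rfm], set(markers), gap_threshold=0.3
        )
        assert total_conflicts(out, set(markers)) == 0
        assert len(log) == 1 and "invert" in log[0]["operation"]
        assert log[0]["length_change_S"] <= 0.02 + 1e-12

    def test_never_increases_conflicts(self, rng):
        markers = [f"m{i}" for i in range(8)]
        pos = np.concatenate(([0.0], np.cumsum(rng.uniform(2, 30, 7))))
        rfm = self._rf_for(pos, markers)
        for _ in range(10):
            orders = [list(rng.permutation(markers)) for _ in range(3)]
            maps = [make_map(o, rfm) for o in orders]
            before = total_conflicts(maps, set(markers))
            out, _ = pre_correct(maps, [rfm] * 3, set(markers))
            assert total_conflicts(out, set(markers)) <= before

    def test_accepted_move_is_best_among_candidates(self):
        """The accepted move matches the best of the exhaustively
        enumerated inversion/transposition candidates."""
        from consmap.conflicts import _segment_moves
        from consmap.core import map_length

        markers = ["m1", "m2", "m3", "m4", "m5", "m6"]
        pos = [0.0, 5.0, 10.0, 65.0, 70.0, 75.0]
        rfm = self._rf_for(pos, markers)
        good = make_map(markers, rfm)
        bad = make_map(["m4", "m5", "m6", "m1", "m2", "m3"], rfm)
        out, log = pre_correct(
            [good, bad], [rfm, rfm], set(markers), gap_threshold=0.3
        )
        # enumerate all candidate moves of the bad map over its large gaps
        best = total_conflicts([good, bad], set(markers))
        for gap_pos, r in enumerate(bad.adjacent_rf):
            if r < 0.3:
                continue
            for _, cand in _segment_moves(bad.order, gap_pos):
                sol = map_length(cand, rfm)
                if sol.length_S <= bad.length_S + 0.02:
                    best = min(
                        best, total_conflicts([good, sol], set(markers))
                    )
        assert total_conflicts(out, set(markers)) == best


class TestOrient:
    def test_orient_maps_aligns_reversals(self):
        shared = {"a", "b", "c", "d"}
        maps = [make_map(["a", "b", "c", "d"]), make_map(["d", "c", "b", "a"])]
        out = orient_maps(maps, shared)
        assert out[1].order == ["a", "b", "c", "d"]
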