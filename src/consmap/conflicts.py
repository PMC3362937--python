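"""Conflict detection and conflict-region delineation between phase-1 maps.

A *conflict* is a pair of shared markers whose relative order differs
between two populations' maps (after orientation alignment).  Overlapping
pairwise conflicts are merged transitively into *conflict regions*: maximal
windows, delimited per dataset, containing the conflicting shared markers,
any shared markers between them, and the interleaved unique markers.  The
markers immediately flanking a window are non-conflicting and are frozen
while the region is re-optimised; a window that reaches the end of a map
has a free (unfrozen) end there.

Before region solving, maps with a large gap (adjacent recombination
fraction above ``gap_threshold``) are screened for whole-segment inversion
or transposition artifacts: reversing or relocating the segment beyond the
gap is accepted when it strictly reduces the total conflict count at a
negligible cost to that map's own length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .core import (
    MapSolution,
    RFMatrix,
    align_orientation,
    discordant_pairs,
    map_length,
)
from .exceptions import ValidationError

__all__ = [
    "ConflictPair",
    "ConflictRegion",
    "orient_maps",
    "detect_conflicts",
    "precedence_cycles",
    "total_conflicts",
    "delineate_regions",
    "pre_correct",
]


@dataclass(frozen=True)
class ConflictPair:
    """Two shared markers observed in opposite relative order."""

    marker_a: str
    marker_b: str
    dataset_ids: frozenset[int]

    def __post_init__(self) -> None:
        if self.marker_a == self.marker_b:
            raise ValidationError("conflict pair must involve two markers")
        if len(self.dataset_ids) < 2:
            raise ValidationError("conflict needs at least two datasets")

    @property
    def markers(self) -> frozenset[str]:
        return frozenset((self.marker_a, self.marker_b))


@dataclass
class ConflictRegion:
    """A delimited window of conflicting shared + interleaved unique markers.

    ``windows[i]`` gives (start, end) positions (inclusive) in dataset i's
    map; ``flanks[i]`` the frozen boundary markers just outside the window
    (``None`` on a side that coincides with the end of the linkage group,
    which stays free).
    """

    shared: list[str]
    windows: dict[int, tuple[int, int]]
    unique_by_dataset: dict[int, list[str]]
    flanks: dict[int, tuple[str | None, str | None]]
    conflict_pairs: list[ConflictPair] = field(default_factory=list)
    #: region shared markers actually present in each dataset's map (maps
    #: may lack some region markers, e.g. after skeleton filtering)
    shared_by_dataset: dict[int, list[str]] | None = None

    def shared_present(self, dataset_id: int, fallback: list[str]) -> set[str]:
        if self.shared_by_dataset is not None:
            return set(self.shared_by_dataset.get(dataset_id, []))
        return set(self.shared) & set(fallback)

    @property
    def k(self) -> int:
        return len(self.shared)

    def n_i(self, dataset_id: int) -> int:
        return len(self.unique_by_dataset.get(dataset_id, []))

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.unique_by_dataset.values())


def orient_maps(
    maps: list[MapSolution], shared: set[str], reference: int = 0
) -> list[MapSolution]:
    """Reverse maps as needed so all agree in orientation with the map at
    ``reference`` on their common shared markers (ties keep the input)."""
    ref_order = [m for m in maps[reference].order if m in shared]
    out = []
    for sol in maps:
        proj = [m for m in sol.order if m in shared]
        if align_orientation(proj, ref_order) != proj:
            out.append(sol.reversed())
        else:
            out.append(sol)
    return out


def detect_conflicts(
    maps: list[MapSolution], shared: set[str]
) -> list[ConflictPair]:
    """All shared marker pairs in opposite relative order in >= 2 maps.

    Each pair of maps is orientation-aligned before comparison; pairs of
    maps with fewer than two common shared markers are skipped.
    """
    if len(maps) < 2:
        raise ValidationError("need at least 2 maps")
    found: dict[frozenset[str], set[int]] = {}
    for i, j in itertools.combinations(range(len(maps)), 2):
        oi = [m for m in maps[i].order if m in shared]
        common = set(oi) & set(maps[j].order)
        if len(common) < 2:
            continue
        oi_c = [m for m in oi if m in common]
        oj_c = [m for m in maps[j].order if m in common]
        oj_c = align_orientation(oj_c, oi_c)
        pos_i = {m: p for p, m in enumerate(oi_c)}
        pos_j = {m: p for p, m in enumerate(oj_c)}
        for a, b in itertools.combinations(oi_c, 2):
            si = pos_i[a] - pos_i[b]
            sj = pos_j[a] - pos_j[b]
            if si * sj < 0:
                found.setdefault(frozenset((a, b)), set()).update((i, j))
    out = []
    for mk, ids in sorted(found.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(mk)
        out.append(ConflictPair(a, b, frozenset(ids)))
    return out


def precedence_cycles(maps: list[MapSolution], shared: set[str]) -> list[list[str]]:
    """Higher-order conflicts: cyclic marker groups in the union precedence
    graph of shared-marker pairs (each map votes a direction for each pair
    it sees).

    Reported as the strongly connected components with >= 3 markers:
    every directed cycle, including order-3+ cycles that no single pair of
    maps exhibits, lies inside one such component.  (Enumerating the
    individual simple cycles is exponential on noisy data and is never
    needed: the whole component must be re-ordered together anyway.)
    """
    g = nx.DiGraph()
    oriented = orient_maps(maps, shared) if len(maps) > 1 else maps
    for sol in oriented:
        proj = [m for m in sol.order if m in shared]
        for a, b in itertools.combinations(proj, 2):
            g.add_edge(a, b)
    return [
        sorted(scc)
        for scc in nx.strongly_connected_components(g)
        if len(scc) >= 3
    ]


def total_conflicts(maps: list[MapSolution], shared: set[str]) -> int:
    """Total count of discordant (map pair, marker pair) incidences."""
    total = 0
    for i, j in itertools.combinations(range(len(maps)), 2):
        oi = [m for m in maps[i].order if m in shared]
        common = set(oi) & set(maps[j].order)
        if len(common) < 2:
            continue
        oi_c = [m for m in oi if m in common]
        oj_c = [m for m in maps[j].order if m in common]
        oj_c = align_orientation(oj_c, oi_c)
        _, dis = discordant_pairs(oi_c, oj_c)
        total += dis
    return total


# ---------------------------------------------------------------------------
# region delineation


def _windows_for(
    maps: list[MapSolution], markers: set[str]
) -> dict[int, tuple[int, int]]:
    """Per dataset, the (start, end) position span covering ``markers``."""
    windows = {}
    for i, sol in enumerate(maps):
        pos = [p for p, m in enumerate(sol.order) if m in markers]
        if pos:
            windows[i] = (min(pos), max(pos))
    return windows


def delineate_regions(
    maps: list[MapSolution],
    conflicts: list[ConflictPair],
    shared: set[str],
) -> list[ConflictRegion]:
    """Merge overlapping conflicts into maximal non-overlapping regions.

    Conflict pairs are grouped transitively: two groups merge when they
    share a marker or their windows overlap in any dataset.  Shared markers
    falling inside a group's window in any dataset join the group (they
    must be re-ordered together), which may expand windows elsewhere; the
    process iterates to a fixed point.
    """
    if not conflicts:
        return []
    # start: one group per conflict pair, merge via union-find on markers
    groups: list[set[str]] = []
    for cp in conflicts:
        merged = None
        for grp in groups:
            if grp & cp.markers:
                grp.update(cp.markers)
                merged = grp
                break
        if merged is None:
            groups.append(set(cp.markers))
    # fixed point: absorb interior shared markers, merge overlapping windows
    changed = True
    while changed:
        changed = False
        windows = [_windows_for(maps, grp) for grp in groups]
        # absorb shared markers lying inside a window
        for grp, win in zip(groups, windows):
            for i, (lo, hi) in win.items():
                inside = {
                    m
                    for m in maps[i].order[lo : hi + 1]
                    if m in shared and m not in grp
                }
                if inside:
                    grp.update(inside)
                    changed = True
        if changed:
            continue
        # merge groups whose windows overlap in some dataset
        merged_any = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            wa, wb = windows[a], windows[b]
            for i in set(wa) & set(wb):
                if wa[i][0] <= wb[i][1] and wb[i][0] <= wa[i][1]:
                    groups[a].update(groups[b])
                    del groups[b]
                    merged_any = True
                    break
            if merged_any:
                break
        changed = merged_any

    regions = []
    for grp in groups:
        windows = _windows_for(maps, grp)
        unique_by_dataset: dict[int, list[str]] = {}
        shared_by_dataset: dict[int, list[str]] = {}
        flanks: dict[int, tuple[str | None, str | None]] = {}
        for i, (lo, hi) in windows.items():
            order = maps[i].order
            unique_by_dataset[i] = [
                m for m in order[lo : hi + 1] if m not in shared
            ]
            shared_by_dataset[i] = [
                m for m in order[lo : hi + 1] if m in shared
            ]
            left = order[lo - 1] if lo > 0 else None
            right = order[hi + 1] if hi + 1 < len(order) else None
            flanks[i] = (left, right)
        # region shared markers in the order of the dataset seeing most of them
        best_ds = max(windows, key=lambda i: len(
            [m for m in maps[i].order if m in grp]))
        ref = [m for m in maps[best_ds].order if m in grp]
        rest = sorted(grp - set(ref))
        pairs = [cp for cp in conflicts if cp.markers <= grp]
        regions.append(
            ConflictRegion(
                ref + rest, windows, unique_by_dataset, flanks, pairs,
                shared_by_dataset,
            )
        )
    regions.sort(key=lambda r: min(w[0] for w in r.windows.values()))
    return regions


# ---------------------------------------------------------------------------
# inversion / transposition pre-correction


def _segment_moves(order: list[str], gap_pos: int) -> list[tuple[str, list[str]]]:
    """Candidate rearrangements around the gap between positions gap_pos
    and gap_pos+1: invert either side in place, or move it to the opposite
    end (in either orientation)."""
    head, tail = order[: gap_pos + 1], order[gap_pos + 1 :]
    cands = [
        ("invert_tail", head + tail[::-1]),
        ("invert_head", head[::-1] + tail),
        ("transpose_tail_front", tail + head),
        ("transpose_tail_front_rev", tail[::-1] + head),
        ("transpose_head_end", tail + head),
        ("transpose_head_end_rev", tail + head[::-1]),
    ]
    seen, out = set(), []
    for name, cand in cands:
        key = tuple(cand)
        if key != tuple(order) and key != tuple(order[::-1]) and key not in seen:
            seen.add(key)
            out.append((name, cand))
    return out


def pre_correct(
    maps: list[MapSolution],
    rf_matrices: list[RFMatrix],
    shared: set[str],
    gap_threshold: float = 0.3,
    length_tolerance: float = 0.02,
    max_rounds: int = 10,
) -> tuple[list[MapSolution], list[dict]]:
    """Screen maps with large gaps for segment inversion/transposition.

    A move is accepted iff it strictly reduces the total conflict count
    across all maps and inflates that map's own length by at most
    ``length_tolerance`` (criterion units).  Returns corrected maps and an
    operations log.
    """
    maps = list(maps)
    log: list[dict] = []
    for _ in range(max_rounds):
        base_conflicts = total_conflicts(maps, shared)
        if base_conflicts == 0:
            break
        best = None  # (new_conflicts, ds, name, candidate MapSolution)
        for ds, (sol, rfm) in enumerate(zip(maps, rf_matrices)):
            for gap_pos, r in enumerate(sol.adjacent_rf):
                if r < gap_threshold:
                    continue
                for name, cand_order in _segment_moves(sol.order, gap_pos):
                    cand = map_length(cand_order, rfm)
                    if cand.length_S > sol.length_S + length_tolerance:
                        continue
                    trial = maps[:ds] + [cand] + maps[ds + 1 :]
                    c = total_conflicts(trial, shared)
                    if c < base_conflicts and (best is None or c < best[0]):
                        best = (c, ds, name, cand)
        if best is None:
            break
        c, ds, name, cand = best
        log.append(
            {
                "dataset": ds,
                "operation": name,
                "conflicts_before": base_conflicts,
                "conflicts_after": c,
                "length_change_S": cand.length_S - maps[ds].length_S,
            }
        )
        maps[ds] = cand
    return maps, log
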