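"""Exact resolution of a single conflict region by tabulation.

A conflict region holds k shared markers (conflicting plus contained) and,
per dataset i, n_i unique markers, bounded by frozen flank markers.  The
naive search space per dataset is (k + n_i)! orders.  The two-stage scheme
cuts this down:

* Stage 1 builds, per dataset, a table of optimal insertions: for every
  ordered pair of anchors (a, b) drawn from the k shared markers plus the
  two flanks, and every subset T of the dataset's unique markers, the
  minimal-length path a -> T -> b and the optimal internal order of T
  (a subset dynamic program over (subset, last-marker) states);
  2^n * ((k+2)(k+1)/2 - 1) entries per dataset.
* Stage 2 enumerates the k! candidate shared orders; for each, every
  dataset independently distributes its unique markers among the k+1
  anchor intervals.  The distribution minimum is found by a
  subset-partition dynamic program over the interval sequence, equivalent
  to (and verified in the tests against) full (k+1)^n enumeration.
  Criterion values are sums of stage-1 table entries.

A region side that coincides with the end of the linkage group has no
flank; the open end is modelled as a virtual marker at zero distance to
everything, so paths may terminate anywhere.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import MapSolution, RFMatrix, discordant_pairs
from .conflicts import ConflictRegion
from .exceptions import FeasibilityError, ValidationError

__all__ = [
    "ComplexityEstimate",
    "InsertionTable",
    "RegionSolution",
    "estimate_complexity",
    "build_insertion_tables",
    "solve_region",
]

#: feasibility bound for the exact scheme: k + n_i < K_PLUS_N_CAP with
#: k < SINGLE_CAP and n_i < SINGLE_CAP
K_PLUS_N_CAP = 15
SINGLE_CAP = 11


@dataclass
class ComplexityEstimate:
    """Operation counts of the two-stage exact scheme for one region."""

    k: int
    n_by_dataset: dict[int, int]
    stage1_entries: dict[int, int]
    stage2_combinations: int
    feasible: bool


def estimate_complexity(
    region: ConflictRegion,
    k_plus_n_cap: int = K_PLUS_N_CAP,
    single_cap: int = SINGLE_CAP,
) -> ComplexityEstimate:
    """Evaluate the tabulation scheme's operation-count formulas.

    Stage 1 holds 2^n * ((k+2)(k+1)/2 - 1) entries per dataset; stage 2
    tests k! * prod_i (k+1)^{n_i} combinations.  The region is feasible for
    the exact solver iff k + n_i < ``k_plus_n_cap`` for every dataset and
    both k and every n_i are below ``single_cap``.
    """
    k = region.k
    n_by = {i: region.n_i(i) for i in region.windows}
    stage1 = {
        i: 2**n * ((k + 2) * (k + 1) // 2 - 1) for i, n in n_by.items()
    }
    stage2 = math.factorial(k)
    for n in n_by.values():
        stage2 *= (k + 1) ** n
    feasible = k < single_cap and all(
        n < single_cap and k + n < k_plus_n_cap for n in n_by.values()
    )
    return ComplexityEstimate(k, n_by, stage1, stage2, feasible)


_VIRTUAL = "__END__"


class _RegionDist:
    """Distance lookup over a region's markers with a virtual open end."""

    def __init__(self, rf: RFMatrix):
        self._rf = rf

    def __call__(self, a: str | None, b: str | None) -> float:
        if a is None or b is None or a == _VIRTUAL or b == _VIRTUAL:
            return 0.0
        return self._rf.dist(a, b)


@dataclass
class InsertionTable:
    """Stage-1 table for one dataset: optimal a -> T -> b insertions.

    ``anchors`` are the region's shared markers present in this dataset
    plus its flanks (``None`` replaces a missing flank at a free end);
    ``uniques`` the dataset's unique markers inside the region.
    """

    dataset_id: int
    anchors: list[str | None]
    uniques: list[str]
    _dist: _RegionDist
    # per source anchor: DP table f[(subset, last)] of path costs
    _dp: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._uindex = {u: t for t, u in enumerate(self.uniques)}
        n = len(self.uniques)
        self._pair = np.zeros((n, n))
        for s, u in enumerate(self.uniques):
            for t, v in enumerate(self.uniques):
                if s != t:
                    self._pair[s, t] = self._dist(u, v)
        for a in self.anchors:
            self._dp[self._key(a)] = self._build_dp(a)

    @staticmethod
    def _key(a: str | None) -> str:
        return _VIRTUAL if a is None else a

    def _build_dp(self, a: str | None) -> np.ndarray:
        """f[S, t]: minimal cost of a path a -> (uniques in S) ending at t."""
        n = len(self.uniques)
        f = np.full((1 << n, max(n, 1)), np.inf)
        for t in range(n):
            f[1 << t, t] = self._dist(a, self.uniques[t])
        for S in range(1, 1 << n):
            for t in range(n):
                if not S >> t & 1 or not np.isfinite(f[S, t]):
                    continue
                base = f[S, t]
                for t2 in range(n):
                    if S >> t2 & 1:
                        continue
                    S2 = S | (1 << t2)
                    cand = base + self._pair[t, t2]
                    if cand < f[S2, t2]:
                        f[S2, t2] = cand
        return f

    def mask(self, T) -> int:
        if isinstance(T, int):
            return T
        return sum(1 << self._uindex[u] for u in T)

    def cost(self, a: str | None, T, b: str | None) -> float:
        """Minimal length of the path a -> T -> b (T a subset of uniques)."""
        S = self.mask(T)
        if S == 0:
            return self._dist(a, b)
        f = self._dp[self._key(a)]
        best = np.inf
        for t in range(len(self.uniques)):
            if S >> t & 1:
                c = f[S, t] + self._dist(self.uniques[t], b)
                if c < best:
                    best = c
        return float(best)

    def order(self, a: str | None, T, b: str | None) -> list[str]:
        """The optimal internal order of T on the path a -> T -> b
        (ties broken toward lexicographically smaller marker names)."""
        S = self.mask(T)
        if S == 0:
            return []
        f = self._dp[self._key(a)]
        n = len(self.uniques)
        # choose the final unique marker
        best: tuple[float, str] | None = None
        last = -1
        for t in range(n):
            if S >> t & 1:
                c = f[S, t] + self._dist(self.uniques[t], b)
                key = (round(c, 12), self.uniques[t])
                if best is None or key < best:
                    best = key
                    last = t
        # backtrack
        seq = [last]
        while S != (1 << last):
            S2 = S ^ (1 << last)
            target = f[S, last]
            pick: tuple[float, str] | None = None
            prev = -1
            for t in range(n):
                if S2 >> t & 1 and np.isfinite(f[S2, t]):
                    c = f[S2, t] + self._pair[t, last]
                    if abs(c - target) < 1e-9:
                        key = (round(f[S2, t], 12), self.uniques[t])
                        if pick is None or key < pick:
                            pick = key
                            prev = t
            seq.append(prev)
            S, last = S2, prev
        return [self.uniques[t] for t in reversed(seq)]


def build_insertion_tables(
    region: ConflictRegion,
    rf_matrices: dict[int, RFMatrix] | list[RFMatrix],
    k_plus_n_cap: int = K_PLUS_N_CAP,
    single_cap: int = SINGLE_CAP,
) -> dict[int, InsertionTable]:
    """Build the stage-1 insertion table for every dataset of the region.

    Raises :class:`FeasibilityError` when the region exceeds the caps, in
    which case the caller should fall back to the GES heuristic.
    """
    est = estimate_complexity(region, k_plus_n_cap, single_cap)
    if not est.feasible:
        raise FeasibilityError(
            f"region with k={est.k}, n={est.n_by_dataset} exceeds the exact "
            "solver caps; use the GES fallback"
        )
    tables = {}
    for i in region.windows:
        rf = rf_matrices[i]
        present = region.shared_present(i, rf.markers)
        anchors: list[str | None] = [
            m for m in region.shared if m in present
        ]
        left, right = region.flanks[i]
        anchors = [left] + anchors + [right]
        tables[i] = InsertionTable(
            i, anchors, list(region.unique_by_dataset.get(i, [])), _RegionDist(rf)
        )
    return tables


@dataclass
class RegionSolution:
    """Optimal consensus suborder of a region with per-dataset placements."""

    shared_suborder: tuple[str, ...]
    #: per dataset: full window content (shared + unique), flanks excluded
    per_dataset_orders: dict[int, list[str]]
    #: per dataset: region length including the frozen-flank edges
    per_dataset_cost: dict[int, float]
    weighted_total: float


def _interval_partition_dp(
    table: InsertionTable, anchors: list[str | None], full_mask: int
) -> tuple[float, list[int]]:
    """Minimal cost of distributing the uniques in ``full_mask`` among the
    len(anchors)-1 intervals; returns (cost, per-interval submasks)."""
    n_int = len(anchors) - 1
    if n_int == 0:
        # no interval at all (single free-end anchor): string everything
        # onto the open side
        cost = table.cost(anchors[0], full_mask, None)
        return cost, [full_mask]
    # h[S] over processed intervals; store choices for reconstruction
    h = {0: 0.0}
    choice: list[dict[int, int]] = []
    for j in range(n_int):
        a, b = anchors[j], anchors[j + 1]
        h2: dict[int, float] = {}
        ch: dict[int, int] = {}
        for S, base in h.items():
            rest = full_mask & ~S
            sub = rest
            while True:
                c = base + table.cost(a, sub, b)
                S2 = S | sub
                if c < h2.get(S2, np.inf) - 1e-15:
                    h2[S2] = c
                    ch[S2] = sub
                if sub == 0:
                    break
                sub = (sub - 1) & rest
        h = h2
        choice.append(ch)
    best = h[full_mask]
    # reconstruct per-interval masks
    masks = []
    S = full_mask
    for j in range(n_int - 1, -1, -1):
        sub = choice[j][S]
        masks.append(sub)
        S &= ~sub
    masks.reverse()
    return float(best), masks


def _dataset_region_cost(
    table: InsertionTable, suborder: tuple[str, ...]
) -> tuple[float, list[str]]:
    """Cost and full window order for one dataset under a candidate shared
    suborder (restricted to the markers this dataset carries)."""
    present = {a for a in table.anchors if a is not None}
    left, right = table.anchors[0], table.anchors[-1]
    inner = [m for m in suborder if m in present]
    anchors = [left] + inner + [right]
    # collapse a missing flank (free end) into the virtual open end, which
    # _RegionDist already treats as zero-distance
    full_mask = table.mask(table.uniques)
    cost, masks = _interval_partition_dp(table, anchors, full_mask)
    # interleave: interval-0 uniques, inner[0], interval-1 uniques, ...;
    # the flanks themselves stay outside the window
    order: list[str] = []
    for j in range(len(anchors) - 1):
        order.extend(table.order(anchors[j], masks[j], anchors[j + 1]))
        if j + 1 < len(anchors) - 1:
            order.append(anchors[j + 1])
    return cost, order


def solve_region(
    region: ConflictRegion,
    tables: dict[int, InsertionTable],
    weights: list[float] | dict[int, float],
    maps: list[MapSolution] | None = None,
) -> RegionSolution:
    """Globally optimal consensus suborder of a conflict region.

    Enumerates every order of the region's shared markers; for each, every
    dataset independently places its unique markers optimally (stage-2 DP
    over stage-1 tables).  Returns the weighted minimum.  Ties between
    shared orders are broken toward the order closest (fewest discordant
    pairs) to the phase-1 maps, then lexicographically.
    """
    if not region.shared:
        raise ValidationError("region has no shared markers")
    if isinstance(weights, list):
        weights = {i: weights[i] for i in region.windows}

    ref_orders = []
    if maps is not None:
        for i in region.windows:
            ref_orders.append([m for m in maps[i].order if m in set(region.shared)])

    per_ds_cache: dict[int, dict[tuple[str, ...], tuple[float, list[str]]]] = {
        i: {} for i in region.windows
    }

    def eval_order(sub: tuple[str, ...]) -> tuple[float, dict, dict]:
        total = 0.0
        orders, costs = {}, {}
        for i in region.windows:
            table = tables[i]
            present = {a for a in table.anchors if a is not None}
            proj = tuple(m for m in sub if m in present)
            cache = per_ds_cache[i]
            if proj not in cache:
                cache[proj] = _dataset_region_cost(table, sub)
            c, o = cache[proj]
            total += weights[i] * c
            costs[i] = c
            orders[i] = o
        return total, orders, costs

    best: tuple | None = None
    for perm in itertools.permutations(region.shared):
        total, orders, costs = eval_order(perm)
        dis = 0
        for ref in ref_orders:
            _, d = discordant_pairs(perm, ref)
            dis += d
        key = (round(total, 12), dis, perm)
        if best is None or key < best[0]:
            best = (key, perm, orders, costs, total)
    _, perm, orders, costs, total = best
    return RegionSolution(perm, orders, costs, float(total))
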