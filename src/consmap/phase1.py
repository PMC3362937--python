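"""Phase-1 per-dataset analysis: marker ordering, stability, filtering.

Ordering a single dataset's markers to minimise the sum of adjacent
recombination fractions is an open-path traveling-salesperson problem on the
RF matrix.  Two solvers are provided:

* ``exact``: Held-Karp dynamic programming over (subset, last-marker)
  states, feasible up to ~16 markers;
* ``heuristic``: multi-start greedy construction followed by 2-opt and
  Or-opt local search, wrapped in a (1+lambda) evolution-strategy loop with
  segment-reversal / segment-translocation perturbations.

Order stability is assessed by jackknife resampling: each replicate drops a
fraction of individuals, re-estimates the RF matrix and re-orders; a marker
is stable when its immediate neighbourhood reproduces the base order.

Skeleton filtering removes markers that (i) are absolutely linked to
another marker, (ii) violate monotone growth of recombination with
subsequent neighbours, or (iii) are unstable under the jackknife.  In
consensus mode only unique markers are removed under these rules; a shared
marker is removed only when absolutely linked to another shared marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Dataset, MapSolution, RFMatrix, align_orientation, map_length
from .exceptions import FeasibilityError, ValidationError
from .twopoint import build_rf_matrix

__all__ = [
    "StabilityReport",
    "order_single",
    "jackknife_stability",
    "skeleton_filter",
    "EXACT_SIZE_CAP",
]

#: largest instance the Held-Karp solver accepts
EXACT_SIZE_CAP = 16


# ---------------------------------------------------------------------------
# path cost and local search on an index permutation


def _path_cost(D: np.ndarray, order: np.ndarray) -> float:
    if len(order) < 2:
        return 0.0
    return float(D[order[:-1], order[1:]].sum())


def _padded(P: np.ndarray) -> np.ndarray:
    """P with a virtual node (index m) at zero distance to everything."""
    m = P.shape[0]
    Q = np.zeros((m + 1, m + 1))
    Q[:m, :m] = P
    return Q


def _best_two_opt(P: np.ndarray) -> tuple[float, int, int]:
    """Best segment-reversal move on the path whose current order is 0..m-1
    under reordered distance matrix P.  Returns (delta, i, j)."""
    m = P.shape[0]
    Q = _padded(P)
    im1 = np.arange(m) - 1
    im1[0] = m
    jp1 = np.arange(m) + 1  # j+1 == m maps to the virtual node
    A = Q[im1][:, :m]          # A[i, j] = d(o[i-1], o[j])
    B = Q[:m][:, jp1]          # B[i, j] = d(o[i], o[j+1])
    c1 = Q[im1, np.arange(m)]  # d(o[i-1], o[i])
    c2 = Q[np.arange(m), jp1]  # d(o[j], o[j+1])
    delta = A + B - c1[:, None] - c2[None, :]
    delta[np.tril_indices(m)] = np.inf  # need i < j
    ij = np.unravel_index(np.argmin(delta), delta.shape)
    return float(delta[ij]), int(ij[0]), int(ij[1])


def _best_or_opt(P: np.ndarray, max_seg: int = 3) -> tuple[float, int, int, int, bool]:
    """Best segment relocation (length 1..max_seg, optionally reversed).

    Returns (delta, i, L, j, reversed) for moving segment [i, i+L-1] so it
    sits immediately before original position j.
    """
    m = P.shape[0]
    Q = _padded(P)
    best = (0.0, -1, 0, -1, False)
    pos = np.arange(m + 1)
    jm1 = pos - 1
    jm1[0] = m  # virtual
    jv = np.where(pos == m, m, pos)
    for L in range(1, min(max_seg, m - 1) + 1):
        for i in range(0, m - L + 1):
            e = i + L - 1
            prev_i = i - 1 if i > 0 else m
            next_e = e + 1 if e + 1 < m else m
            removed = Q[prev_i, i] + Q[e, next_e]
            bridge = Q[prev_i, next_e]
            ins_f = Q[jm1, i] + Q[e, jv]   # forward orientation
            ins_r = Q[jm1, e] + Q[i, jv]   # reversed orientation
            broken = Q[jm1, jv]
            delta_f = bridge + ins_f - broken - removed
            delta_r = bridge + ins_r - broken - removed
            # exclude no-op / interior insertion points
            bad = (pos >= i) & (pos <= e + 1)
            delta_f[bad] = np.inf
            delta_r[bad] = np.inf
            jf = int(np.argmin(delta_f))
            jr = int(np.argmin(delta_r))
            if delta_f[jf] < best[0] - 1e-12:
                best = (float(delta_f[jf]), i, L, jf, False)
            if delta_r[jr] < best[0] - 1e-12:
                best = (float(delta_r[jr]), i, L, jr, True)
    return best


def _apply_or_opt(order: np.ndarray, i: int, L: int, j: int, rev: bool) -> np.ndarray:
    seg = order[i : i + L][::-1] if rev else order[i : i + L]
    rest = np.concatenate([order[:i], order[i + L :]])
    j_adj = j if j < i else j - L
    return np.concatenate([rest[:j_adj], seg, rest[j_adj:]])


def _local_search(D: np.ndarray, order: np.ndarray) -> np.ndarray:
    """2-opt + Or-opt descent to a local optimum."""
    order = order.copy()
    while True:
        P = D[np.ix_(order, order)]
        d2, i, j = _best_two_opt(P)
        if d2 < -1e-12:
            order[i : j + 1] = order[i : j + 1][::-1]
            continue
        d3, i, L, j, rev = _best_or_opt(P)
        if d3 < -1e-12:
            order = _apply_or_opt(order, i, L, j, rev)
            continue
        return order


def _greedy_order(D: np.ndarray, start: int) -> np.ndarray:
    m = D.shape[0]
    order = np.empty(m, dtype=int)
    order[0] = start
    used = np.zeros(m, dtype=bool)
    used[start] = True
    for t in range(1, m):
        d = D[order[t - 1]].copy()
        d[used] = np.inf
        order[t] = int(np.argmin(d))
        used[order[t]] = True
    return order


def _perturb(order: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random segment reversal or translocation."""
    m = len(order)
    out = order.copy()
    L = int(rng.integers(2, max(3, m // 3) + 1))
    i = int(rng.integers(0, m - L + 1))
    if rng.random() < 0.5:
        out[i : i + L] = out[i : i + L][::-1]
    else:
        seg = out[i : i + L]
        rest = np.concatenate([out[:i], out[i + L :]])
        j = int(rng.integers(0, len(rest) + 1))
        out = np.concatenate([rest[:j], seg, rest[j:]])
    return out


def _heuristic_order(
    D: np.ndarray,
    rng: np.random.Generator,
    n_starts: int = 5,
    stall_limit: int = 40,
    max_iters: int = 400,
) -> np.ndarray:
    m = D.shape[0]
    starts = rng.choice(m, size=min(n_starts, m), replace=False)
    best = None
    best_cost = np.inf
    for s in starts:
        cand = _local_search(D, _greedy_order(D, int(s)))
        cost = _path_cost(D, cand)
        if cost < best_cost - 1e-15:
            best, best_cost = cand, cost
    stall = 0
    for _ in range(max_iters):
        if stall >= stall_limit:
            break
        cand = _local_search(D, _perturb(best, rng))
        cost = _path_cost(D, cand)
        if cost < best_cost - 1e-12:
            best, best_cost = cand, cost
            stall = 0
        else:
            stall += 1
    return best


def _held_karp(D: np.ndarray) -> np.ndarray:
    """Exact minimum open Hamiltonian path by subset dynamic programming."""
    m = D.shape[0]
    if m > EXACT_SIZE_CAP:
        raise FeasibilityError(
            f"exact solver capped at {EXACT_SIZE_CAP} markers, got {m}"
        )
    if m == 1:
        return np.array([0])
    size = 1 << m
    dp = np.full((size, m), np.inf)
    parent = np.full((size, m), -1, dtype=np.int32)
    for j in range(m):
        dp[1 << j, j] = 0.0
    subsets = sorted(range(1, size), key=lambda s: bin(s).count("1"))
    for S in subsets:
        row = dp[S]
        if not np.isfinite(row).any():
            continue
        members = [i for i in range(m) if S >> i & 1]
        if len(members) == m:
            continue
        for j in range(m):
            if S >> j & 1:
                continue
            cand = row[members] + D[members, j]
            k = int(np.argmin(cand))
            S2 = S | (1 << j)
            if cand[k] < dp[S2, j]:
                dp[S2, j] = cand[k]
                parent[S2, j] = members[k]
    full = size - 1
    j = int(np.argmin(dp[full]))
    order = [j]
    S = full
    while parent[S, j] >= 0:
        p = int(parent[S, j])
        S ^= 1 << j
        j = p
        order.append(j)
    return np.array(order[::-1])


def _normalize_orientation(order: list[str]) -> list[str]:
    """Deterministic orientation: first marker name sorts before the last."""
    if order and order[-1] < order[0]:
        return order[::-1]
    return order


def order_single(
    rf: RFMatrix,
    solver: str = "auto",
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> MapSolution:
    """Order one dataset's markers to minimise the map length.

    ``solver`` is ``"exact"`` (Held-Karp, <= 16 markers), ``"heuristic"``
    (ES + 2-opt/Or-opt), or ``"auto"`` (exact when small enough).
    """
    m = len(rf.markers)
    if m == 0:
        raise ValidationError("empty RF matrix")
    D = rf.rf
    if solver == "auto":
        solver = "exact" if m <= 12 else "heuristic"
    if solver == "exact":
        idx = _held_karp(D)
    elif solver == "heuristic":
        rng = np.random.default_rng(rng)
        idx = _heuristic_order(D, rng, **kwargs)
    else:
        raise ValidationError(f"unknown solver {solver!r}")
    order = _normalize_orientation([rf.markers[i] for i in idx])
    return map_length(order, rf)


# ---------------------------------------------------------------------------
# jackknife stability


@dataclass
class StabilityReport:
    """Per-marker neighbourhood-retention frequencies over jackknife
    replicates."""

    frequencies: dict[str, float]
    n_replicates: int
    drop_fraction: float

    def frequency(self, marker: str) -> float:
        return self.frequencies.get(marker, 0.0)


def _neighbors(order: list[str]) -> dict[str, frozenset]:
    out = {}
    for i, mkr in enumerate(order):
        nb = []
        if i > 0:
            nb.append(order[i - 1])
        if i + 1 < len(order):
            nb.append(order[i + 1])
        out[mkr] = frozenset(nb)
    return out


def jackknife_stability(
    dataset: Dataset,
    base_order: MapSolution,
    n_replicates: int = 100,
    drop_fraction: float = 0.2,
    rng: np.random.Generator | int | None = None,
    solver: str = "auto",
    min_informative: int = 10,
    **solver_kwargs,
) -> StabilityReport:
    """Jackknife the individuals, re-order each replicate, and score each
    marker by how often its immediate neighbourhood matches the base order."""
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if not 0.0 < drop_fraction < 1.0:
        raise ValidationError("drop_fraction must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    n = dataset.sample_size
    keep_n = max(2, int(round((1.0 - drop_fraction) * n)))
    base_nb = _neighbors(base_order.order)
    successes = {m: 0 for m in base_order.order}
    for _ in range(n_replicates):
        cols = rng.choice(n, size=keep_n, replace=False)
        sub = Dataset(
            dataset.id,
            dataset.cross_type,
            list(dataset.markers),
            dataset.genotypes[:, cols],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfm = build_rf_matrix(sub, min_informative=min_informative)
        sol = order_single(rfm, solver=solver, rng=rng, **solver_kwargs)
        rep_order = align_orientation(sol.order, base_order.order)
        rep_nb = _neighbors(rep_order)
        for m in successes:
            if m in rep_nb and rep_nb[m] == base_nb[m]:
                successes[m] += 1
    freqs = {m: successes[m] / n_replicates for m in successes}
    return StabilityReport(freqs, n_replicates, drop_fraction)


# ---------------------------------------------------------------------------
# skeleton filtering


def _monotone_violations(
    rf: RFMatrix,
    order: list[str],
    window: int = 4,
) -> set[str]:
    """Markers whose recombination with subsequent neighbours fails to grow
    monotonically (within a 2*SE tolerance), scanned in both directions."""
    bad: set[str] = set()
    idx = [rf.index(m) for m in order]
    R = rf.rf[np.ix_(idx, idx)]
    N = rf.n_informative[np.ix_(idx, idx)]
    m = len(order)
    for p in range(m):
        for direction in (1, -1):
            prev = 0.0
            for d in range(1, window + 1):
                q = p + direction * d
                if not 0 <= q < m:
                    break
                r = R[p, q]
                n = max(int(N[p, q]), 1)
                se = np.sqrt(max(r * (1 - r), 1e-6) / n)
                if r < prev - 2.0 * se:
                    bad.add(order[p])
                    break
                prev = max(prev, r)
    return bad


def skeleton_filter(
    dataset: Dataset,
    map_solution: MapSolution,
    stability: StabilityReport | None,
    rf: RFMatrix,
    consensus_mode: bool = False,
    shared_markers: set[str] | None = None,
    stability_threshold: float = 0.7,
    monotone_window: int = 4,
) -> tuple[MapSolution, list[dict]]:
    """Remove markers failing the skeleton rules; returns the filtered map
    and a removal log of ``{"marker", "reason"}`` records.

    In ``consensus_mode`` only unique markers are removed under rules
    (ii)/(iii); absolute-linkage twins (rule i) also remove a shared marker
    when its twin is shared, keeping the higher-stability copy.
    """
    shared = shared_markers or set()
    order = list(map_solution.order)
    removals: list[dict] = []

    def stab(m: str) -> float:
        return stability.frequency(m) if stability is not None else 1.0

    def removable(m: str, twin: str | None = None) -> bool:
        if not consensus_mode:
            return True
        if m not in shared:
            return True
        # shared marker: removable only as an absolute-linkage twin of
        # another shared marker
        return twin is not None and twin in shared

    # rule (i): absolutely linked twins -- drop the lower-stability copy
    changed = True
    while changed:
        changed = False
        for a, b in zip(order[:-1], order[1:]):
            if rf.dist(a, b) > 0.0:
                continue
            # prefer to drop an unmovable-free marker; lower stability first
            cand = sorted([a, b], key=lambda m: (stab(m), m))
            victim = None
            for c in cand:
                twin = b if c == a else a
                if removable(c, twin=twin):
                    victim = c
                    break
            if victim is None:
                continue
            order.remove(victim)
            removals.append({"marker": victim, "reason": "absolutely_linked"})
            changed = True
            break

    # rule (ii): monotone growth of recombination with subsequent neighbours
    for m in sorted(_monotone_violations(rf, order, monotone_window)):
        if m in order and removable(m):
            order.remove(m)
            removals.append({"marker": m, "reason": "non_monotone"})

    # rule (iii): unstable location under jackknife
    if stability is not None:
        for m in list(order):
            if stab(m) < stability_threshold and removable(m):
                order.remove(m)
                removals.append({"marker": m, "reason": "unstable"})

    return map_length(order, rf), removals
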