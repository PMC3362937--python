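"""Guided evolution strategy (GES) for the synchronized ordering problem.

Candidate orders g of the shared markers are generated by a
multi-parametric mutation operator (segment reversal, segment
translocation, point exchange, with mutation sites biased toward
low-confidence zones, i.e. long adjacent intervals).  Because evaluating
the main criterion S(g) requires placing every dataset's unique markers
around the shared anchors, mutants are first screened by the cheap
skeleton criterion S_shared(g): only candidates with S_shared(g) <= q are
fully evaluated.  The threshold q is learned along the trajectory from the
recorded (S_shared, S) pairs of accepted solutions.

Unique-marker placement under the anchor constraint uses cheapest-insertion
construction followed by three local-search moves that never disturb the
anchor order: "Reinsert" (move one unique marker to its best slot),
"Reverse-Reinsert" (relocate a short run of unique markers reversed) and
"Exchange 1*1" (swap two unique markers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConsensusProblem,
    ConsensusSolution,
    MapSolution,
    RFMatrix,
    SharedOrder,
    map_length,
    skeleton_criterion,
)
from .conflicts import ConflictRegion
from .exceptions import ValidationError
from .local_exact import RegionSolution

__all__ = [
    "GESParams",
    "ThresholdState",
    "mutate",
    "place_unique",
    "ges_consensus",
    "solve_region_ges",
]


@dataclass
class GESParams:
    """Mutation and search-control parameters of the GES heuristic.

    The six mutation parameters: rates of the three operators (segment
    reversal, segment translocation, point swap), the mean segment lengths
    of the two segment operators, and the mutation-site bias exponent
    (sites are drawn with probability proportional to the local interval
    length raised to ``site_bias``; 0 disables the bias).
    """

    reversal_rate: float = 0.6
    reversal_len_mean: float = 4.0
    transloc_rate: float = 0.3
    transloc_len_mean: float = 3.0
    swap_rate: float = 0.15
    site_bias: float = 1.0
    mu: int = 1
    lam: int = 10
    #: total mutant budget and mutants-without-improvement stall limit
    max_iters: int = 3000
    stall_limit: int = 2000
    #: budget for the skeleton-only search producing g**
    skeleton_iters: int = 400
    q_margin: float = 0.02

    def __post_init__(self) -> None:
        for name in ("reversal_rate", "transloc_rate", "swap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not self.lam >= self.mu >= 1:
            raise ValidationError("need lambda >= mu >= 1")
        if self.q_margin < 0:
            raise ValidationError("q_margin must be >= 0")


@dataclass
class ThresholdState:
    """Learned screening threshold q over recorded (S_shared, S) pairs.

    q sits a multiplicative margin above the largest S_shared among the
    five best recorded solutions (by full criterion).  The margin starts
    at ``margin`` and doubles on prolonged stalls (screening too hard),
    snapping back to the base value whenever an improvement is accepted —
    so the screen stays tight while progress is made and opens up when
    the skeleton criterion stops being informative.
    """

    margin: float = 0.02
    pairs: list[tuple[float, float]] = field(default_factory=list)
    q: float = np.inf
    _margin_now: float = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._margin_now is None:
            self._margin_now = self.margin

    def record(self, s_shared: float, s_full: float) -> None:
        self.pairs.append((float(s_shared), float(s_full)))
        self._margin_now = self.margin
        self._update_q()

    def relax(self, factor: float = 2.0, cap: float = 4.0) -> None:
        self._margin_now = min(self._margin_now * factor, cap)
        self._update_q()

    def _update_q(self) -> None:
        best = sorted(self.pairs, key=lambda p: p[1])[:5]
        self.q = max(p[0] for p in best) * (1.0 + self._margin_now)


def _segment_length(mean: float, m: int, rng: np.random.Generator) -> int:
    excess = max(mean - 2.0, 0.0)
    if excess <= 0:
        L = 2
    else:
        L = 2 + int(rng.geometric(1.0 / (excess + 1.0))) - 1
    return min(L, m)


def _pick_site(
    m: int, L: int, rng: np.random.Generator, weights: np.ndarray | None, bias: float
) -> int:
    hi = m - L
    if hi <= 0:
        return 0
    if weights is None or bias <= 0:
        return int(rng.integers(0, hi + 1))
    w = np.asarray(weights[: hi + 1], dtype=float) + 1e-9
    p = w**bias
    p /= p.sum()
    return int(rng.choice(hi + 1, p=p))


def mutate(
    g_best: SharedOrder,
    params: GESParams,
    rng: np.random.Generator | int | None = None,
    interval_weights: np.ndarray | None = None,
) -> SharedOrder:
    """Generate a mutant order from g_best.

    Operators fire independently with their configured rates; when every
    rate is zero the input is returned unchanged.  ``interval_weights``
    (one per position, e.g. the mean adjacent recombination fraction)
    biases mutation sites toward uncertain zones.
    """
    rng = np.random.default_rng(rng)
    seq = list(g_best.sequence)
    m = len(seq)
    if m < 2:
        return SharedOrder(tuple(seq))
    total_rate = params.reversal_rate + params.transloc_rate + params.swap_rate
    fired = False
    if rng.random() < params.reversal_rate:
        L = _segment_length(params.reversal_len_mean, m, rng)
        i = _pick_site(m, L, rng, interval_weights, params.site_bias)
        seq[i : i + L] = seq[i : i + L][::-1]
        fired = True
    if rng.random() < params.transloc_rate:
        L = _segment_length(params.transloc_len_mean, m, rng)
        i = _pick_site(m, L, rng, interval_weights, params.site_bias)
        seg = seq[i : i + L]
        rest = seq[:i] + seq[i + L :]
        j = int(rng.integers(0, len(rest) + 1))
        seq = rest[:j] + seg + rest[j:]
        fired = True
    if rng.random() < params.swap_rate and m >= 2:
        i, j = rng.choice(m, size=2, replace=False)
        seq[i], seq[j] = seq[j], seq[i]
        fired = True
    if not fired and total_rate > 0:
        L = _segment_length(params.reversal_len_mean, m, rng)
        i = _pick_site(m, L, rng, interval_weights, params.site_bias)
        seq[i : i + L] = seq[i : i + L][::-1]
    return SharedOrder(tuple(seq))


# ---------------------------------------------------------------------------
# anchor-constrained placement of unique markers


class _Placer:
    """Cheapest insertion + local search keeping anchor order fixed."""

    def __init__(
        self,
        D: np.ndarray,
        anchors: list[int],
        uniques: list[int],
        clamp_left: bool = False,
        clamp_right: bool = False,
        sequential: bool = False,
    ):
        self.D = D
        self.anchors = list(anchors)
        self.clamp_left = clamp_left
        self.clamp_right = clamp_right
        self.order = list(anchors)
        self._insert_all(list(uniques), sequential)
        self._local_search()

    # -- helpers ---------------------------------------------------------
    def _slot_range(self) -> tuple[int, int]:
        """Allowed insertion slots [lo, hi]; slot s inserts before
        position s."""
        lo, hi = 0, len(self.order)
        if self.anchors:
            if self.clamp_left:
                lo = self.order.index(self.anchors[0]) + 1
            if self.clamp_right:
                hi = self.order.index(self.anchors[-1])
        return lo, hi

    def _insertion_cost(self, u: int, s: int) -> float:
        D, o = self.D, self.order
        left = D[o[s - 1], u] if s > 0 else 0.0
        right = D[u, o[s]] if s < len(o) else 0.0
        broken = D[o[s - 1], o[s]] if 0 < s < len(o) else 0.0
        return left + right - broken

    def _insert_all(self, uniques: list[int], sequential: bool = False) -> None:
        pending = list(uniques)
        while pending:
            lo, hi = self._slot_range()
            best = None
            cands = pending[:1] if sequential else pending
            for u in cands:
                for s in range(lo, hi + 1):
                    c = self._insertion_cost(u, s)
                    if best is None or c < best[0] - 1e-15:
                        best = (c, u, s)
            _, u, s = best
            self.order.insert(s, u)
            pending.remove(u)

    def cost(self) -> float:
        o = self.order
        if len(o) < 2:
            return 0.0
        return float(self.D[o[:-1], o[1:]].sum()) if isinstance(o, np.ndarray) else float(
            sum(self.D[a, b] for a, b in zip(o[:-1], o[1:]))
        )

    # -- local search moves ---------------------------------------------
    def _removal_gain(self, p: int, L: int = 1) -> float:
        D, o = self.D, self.order
        left = D[o[p - 1], o[p]] if p > 0 else 0.0
        right = D[o[p + L - 1], o[p + L]] if p + L < len(o) else 0.0
        bridge = (
            D[o[p - 1], o[p + L]] if 0 < p and p + L < len(o) else 0.0
        )
        return left + right - bridge

    def _try_reinsert(self, anchor_set: set[int], seg_len: int, reverse: bool) -> bool:
        o = self.order
        for p in range(len(o) - seg_len + 1):
            seg = o[p : p + seg_len]
            if any(x in anchor_set for x in seg):
                continue
            gain = self._removal_gain(p, seg_len)
            rest = o[:p] + o[p + seg_len :]
            ins = seg[::-1] if reverse else seg
            saved = self.order
            self.order = rest
            lo, hi = self._slot_range()
            best = None
            for s in range(lo, hi + 1):
                D = self.D
                left = D[rest[s - 1], ins[0]] if s > 0 else 0.0
                right = D[ins[-1], rest[s]] if s < len(rest) else 0.0
                broken = D[rest[s - 1], rest[s]] if 0 < s < len(rest) else 0.0
                inner = sum(
                    D[a, b] for a, b in zip(ins[:-1], ins[1:])
                ) - sum(D[a, b] for a, b in zip(seg[:-1], seg[1:]))
                c = left + right - broken + inner
                if best is None or c < best[0] - 1e-15:
                    best = (c, s)
            c, s = best
            if c < gain - 1e-12:
                self.order = rest[:s] + ins + rest[s:]
                return True
            self.order = saved
        return False

    def _try_exchange(self, anchor_set: set[int]) -> bool:
        o = self.order
        D = self.D
        upos = [p for p, x in enumerate(o) if x not in anchor_set]
        base = self.cost()
        for ai in range(len(upos)):
            for bi in range(ai + 1, len(upos)):
                p, q = upos[ai], upos[bi]
                o[p], o[q] = o[q], o[p]
                if self.cost() < base - 1e-12:
                    return True
                o[p], o[q] = o[q], o[p]
        return False

    def _local_search(self, max_passes: int = 60) -> None:
        anchor_set = set(self.anchors)
        for _ in range(max_passes):
            if self._try_reinsert(anchor_set, 1, False):
                continue
            if self._try_reinsert(anchor_set, 2, True):
                continue
            if self._try_reinsert(anchor_set, 2, False):
                continue
            if self._try_reinsert(anchor_set, 3, True):
                continue
            if self._try_reinsert(anchor_set, 3, False):
                continue
            if self._try_exchange(anchor_set):
                continue
            break


def place_unique(
    g: SharedOrder,
    rf: RFMatrix,
    shared: set[str],
    clamp_left: bool = False,
    clamp_right: bool = False,
) -> MapSolution:
    """Optimally-placed full map for one dataset embedding g(i) exactly.

    Unique markers are inserted by cheapest insertion and improved by the
    Reinsert / Reverse-Reinsert / Exchange 1*1 moves; the shared-marker
    order is preserved throughout.
    """
    present = set(rf.markers)
    anchors = [m for m in g.sequence if m in present]
    uniques = [m for m in rf.markers if m not in shared]
    if not anchors:
        raise ValidationError("g(i) is empty for this dataset")
    a_idx = [rf.index(m) for m in anchors]
    u_idx = [rf.index(m) for m in uniques]
    # two construction strategies (cheapest vs sequential insertion) give
    # different local-search basins; keep the better endpoint
    placers = [
        _Placer(rf.rf, a_idx, u_idx, clamp_left, clamp_right),
        _Placer(rf.rf, a_idx, u_idx, clamp_left, clamp_right, sequential=True),
    ]
    placer = min(placers, key=lambda p: p.cost())
    order = [rf.markers[i] for i in placer.order]
    return map_length(order, rf)


# ---------------------------------------------------------------------------
# the GES loop


def _interval_weights(g: SharedOrder, problem: ConsensusProblem) -> np.ndarray:
    """Mean adjacent recombination fraction at each position of g (used to
    bias mutation sites toward loosely supported zones)."""
    m = len(g)
    acc = np.zeros(m)
    cnt = np.zeros(m)
    for ds, rfm in zip(problem.datasets, problem.rf_matrices):
        present = set(rfm.markers)
        proj = [(p, mk) for p, mk in enumerate(g.sequence) if mk in present]
        for (p1, m1), (p2, m2) in zip(proj[:-1], proj[1:]):
            d = rfm.dist(m1, m2)
            acc[p1] += d
            cnt[p1] += 1
            acc[p2] += d
            cnt[p2] += 1
    with np.errstate(invalid="ignore"):
        w = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return w


def _es_minimize(
    g_init: SharedOrder,
    objective,
    params: GESParams,
    rng: np.random.Generator,
    budget: int,
    interval_weights: np.ndarray | None = None,
) -> tuple[SharedOrder, float]:
    """Plain elitist ES on a single cheap objective (used for g**)."""
    best = g_init
    best_val = objective(best)
    for _ in range(budget):
        cand = mutate(best, params, rng, interval_weights)
        v = objective(cand)
        if v < best_val - 1e-12:
            best, best_val = cand, v
    return best, best_val


def _full_eval(
    g: SharedOrder, problem: ConsensusProblem
) -> tuple[float, list[MapSolution]]:
    shared = problem.shared_markers
    maps = []
    total = 0.0
    for rfm, w in zip(problem.rf_matrices, problem.weights):
        sol = place_unique(g, rfm, shared)
        maps.append(sol)
        total += w * sol.length_S
    return float(total), maps


def _initial_shared_order(problem: ConsensusProblem) -> SharedOrder:
    """Initial g: shared markers sorted by mean normalised position across
    the (orientation-aligned) datasets."""
    from .conflicts import orient_maps  # deferred: avoid cycle at import

    shared = problem.shared_markers
    maps = [
        MapSolution(rfm.markers, list(np.diag(rfm.rf, k=1)))
        for rfm in problem.rf_matrices
    ]
    maps = orient_maps(maps, shared)
    acc: dict[str, list[float]] = {m: [] for m in shared}
    for sol in maps:
        proj = [m for m in sol.order if m in shared]
        if len(proj) < 2:
            continue
        for p, mk in enumerate(proj):
            acc[mk].append(p / (len(proj) - 1))
    seq = sorted(shared, key=lambda m: (np.mean(acc[m]) if acc[m] else 0.5, m))
    return SharedOrder(tuple(seq))


def ges_consensus(
    problem: ConsensusProblem,
    g_star: SharedOrder | None = None,
    params: GESParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[ConsensusSolution, dict]:
    """Run the GES over the whole chromosome.

    ``g_star`` is the starting shared order (typically the merged local
    solution); a quick skeleton-only optimum g** is computed as well and
    the better of the two (under the full criterion) seeds the search.
    Returns the best solution found and an info dict with the incumbent
    trajectory, the screening statistics and the threshold state.
    """
    if not problem.shared_markers:
        raise ValidationError("problem has no shared markers")
    params = params or GESParams()
    rng = np.random.default_rng(rng)

    g_seed = g_star if g_star is not None else _initial_shared_order(problem)
    iw = _interval_weights(g_seed, problem)
    g_skel, _ = _es_minimize(
        g_seed,
        lambda g: skeleton_criterion(g, problem),
        params,
        rng,
        params.skeleton_iters,
        iw,
    )
    candidates = [g_seed, g_skel] if g_star is not None else [g_skel, g_seed]
    evals = [_full_eval(g, problem) for g in candidates]
    best_i = int(np.argmin([e[0] for e in evals]))
    g_best = candidates[best_i]
    S_best, maps_best = evals[best_i]

    state = ThresholdState(margin=params.q_margin)
    state.record(skeleton_criterion(g_best, problem), S_best)
    trajectory = [S_best]
    n_generated = n_evaluated = 0
    stall = 0
    relax_every = max(params.stall_limit // 8, 25)
    iw = _interval_weights(g_best, problem)
    while n_generated < params.max_iters and stall < params.stall_limit:
        for _ in range(params.lam):
            if n_generated >= params.max_iters or stall >= params.stall_limit:
                break
            cand = mutate(g_best, params, rng, iw)
            n_generated += 1
            s_sh = skeleton_criterion(cand, problem)
            if s_sh <= state.q:
                n_evaluated += 1
                S, maps = _full_eval(cand, problem)
                if S < S_best - 1e-12:
                    g_best, S_best, maps_best = cand, S, maps
                    state.record(s_sh, S)
                    iw = _interval_weights(g_best, problem)
                    stall = 0
                else:
                    stall += 1
            else:
                stall += 1
            if stall and stall % relax_every == 0:
                state.relax()
            trajectory.append(S_best)

    solution = ConsensusSolution(g_best, maps_best, list(problem.weights))
    info = {
        "trajectory": trajectory,
        "n_generated": n_generated,
        "n_evaluated": n_evaluated,
        "threshold_state": state,
    }
    return solution, info


# ---------------------------------------------------------------------------
# GES restricted to one conflict region


def solve_region_ges(
    region: ConflictRegion,
    rf_matrices: list[RFMatrix],
    weights: list[float] | dict[int, float],
    params: GESParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> RegionSolution:
    """Heuristic counterpart of the exact region solver for regions above
    the exact caps: GES over the region's shared suborders with
    anchor-constrained placement of the region's unique markers."""
    params = params or GESParams(max_iters=800, stall_limit=400)
    rng = np.random.default_rng(rng)
    if isinstance(weights, list):
        weights = {i: weights[i] for i in region.windows}

    shared_set = set(region.shared)

    def eval_ds(i: int, sub: tuple[str, ...]) -> tuple[float, list[str]]:
        rfm = rf_matrices[i]
        present = region.shared_present(i, rfm.markers)
        left, right = region.flanks[i]
        inner = [m for m in sub if m in present]
        anchors = ([left] if left else []) + inner + ([right] if right else [])
        uniques = region.unique_by_dataset.get(i, [])
        if not anchors:
            anchors = []
        a_idx = [rfm.index(m) for m in anchors]
        u_idx = [rfm.index(m) for m in uniques]
        placer = _Placer(
            rfm.rf,
            a_idx,
            u_idx,
            clamp_left=left is not None,
            clamp_right=right is not None,
        )
        cost = placer.cost()
        order = [rfm.markers[t] for t in placer.order]
        # strip the flanks; they belong outside the window
        if left is not None:
            order = order[1:]
        if right is not None:
            order = order[:-1]
        return cost, order

    def eval_full(sub: tuple[str, ...]) -> tuple[float, dict, dict]:
        total = 0.0
        orders, costs = {}, {}
        for i in region.windows:
            c, o = eval_ds(i, sub)
            total += weights[i] * c
            costs[i] = c
            orders[i] = o
        return total, orders, costs

    def eval_shared(sub: tuple[str, ...]) -> float:
        total = 0.0
        for i in region.windows:
            rfm = rf_matrices[i]
            present = region.shared_present(i, rfm.markers)
            left, right = region.flanks[i]
            path = [left] * (left is not None) + [
                m for m in sub if m in present
            ] + [right] * (right is not None)
            if len(path) >= 2:
                total += weights[i] * map_length(path, rfm).length_S
        return total

    g_best = tuple(region.shared)
    S_best, orders_best, costs_best = eval_full(g_best)
    state = ThresholdState(margin=params.q_margin)
    state.record(eval_shared(g_best), S_best)
    stall = 0
    n = 0
    relax_every = max(params.stall_limit // 8, 25)
    g_obj = SharedOrder(g_best)
    while n < params.max_iters and stall < params.stall_limit:
        cand = mutate(g_obj, params, rng).sequence
        n += 1
        if eval_shared(cand) <= state.q:
            S, orders, costs = eval_full(cand)
            if S < S_best - 1e-12:
                g_best, S_best = cand, S
                orders_best, costs_best = orders, costs
                g_obj = SharedOrder(g_best)
                state.record(eval_shared(cand), S)
                stall = 0
            else:
                stall += 1
        else:
            stall += 1
        if stall and stall % relax_every == 0:
            state.relax()
    return RegionSolution(tuple(g_best), orders_best, costs_best, float(S_best))
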