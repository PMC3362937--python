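"""Two-phase consensus-mapping pipeline.

Phase 1 orders each dataset independently (TSP over its RF matrix) and
optionally jackknifes and filters the maps.  Phase 2 aligns orientations,
pre-corrects large-gap inversion/transposition artifacts, detects
conflicts between the individual maps, delineates conflict regions, and
re-optimises each region under the shared-order constraint — exactly when
the region is small enough, by GES otherwise — before an optional global
GES polish over the whole chromosome.

The *cost of consensus* of a dataset is the inflation of its map length
imposed by the consensus order relative to its own phase-1 optimum; it is
reported per dataset with a per-marker attribution, and markers whose cost
is unaffordable can be proposed for removal.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .conflicts import (
    ConflictPair,
    ConflictRegion,
    delineate_regions,
    detect_conflicts,
    orient_maps,
    pre_correct,
    precedence_cycles,
)
from .core import (
    ConsensusProblem,
    ConsensusSolution,
    Dataset,
    MapSolution,
    RFMatrix,
    SharedOrder,
    align_orientation,
    conflict_free,
    map_length,
)
from .exceptions import ConsmapError, ValidationError
from .ges import GESParams, ges_consensus, solve_region_ges
from .local_exact import build_insertion_tables, estimate_complexity, solve_region
from .phase1 import StabilityReport, jackknife_stability, order_single, skeleton_filter

__all__ = [
    "PipelineConfig",
    "CostReport",
    "DatasetCost",
    "RunResult",
    "run_consensus",
    "compute_weights",
    "suggest_removals",
    "recovery_coefficient",
    "order_violations",
    "build_integral_map",
    "merge_shared_orders",
]


@dataclass
class PipelineConfig:
    """Tunable knobs of the consensus pipeline."""

    phase1_solver: str = "auto"
    #: jackknife replicates per dataset; 0 disables stability analysis
    jackknife_replicates: int = 0
    drop_fraction: float = 0.2
    stability_threshold: float = 0.7
    #: apply skeleton filtering (rules i-iii) in consensus mode
    skeleton_filtering: bool = True
    gap_threshold: float = 0.3
    pre_correct_tolerance: float = 0.02
    #: operational caps for the exact region solver (enumeration is k! *
    #: 3^n per dataset internally; these keep single regions sub-second)
    exact_k_max: int = 6
    exact_n_max: int = 7
    weights_mode: str = "equal"
    ges: GESParams = field(
        default_factory=lambda: GESParams(
            max_iters=600, stall_limit=300, skeleton_iters=200
        )
    )
    high_cost_threshold_cM: float = 10.0
    seed: int | None = None


@dataclass
class DatasetCost:
    dataset_id: int
    L_ind_cM: float
    L_cons_cM: float
    delta_cM: float
    #: per-marker share of delta (half of each incident-edge change)
    attribution_cM: dict[str, float]
    high_cost: bool


@dataclass
class CostReport:
    per_dataset: list[DatasetCost]
    threshold_cM: float

    @property
    def total_delta_cM(self) -> float:
        return float(sum(d.delta_cM for d in self.per_dataset))

    def high_cost_datasets(self) -> list[int]:
        return [d.dataset_id for d in self.per_dataset if d.high_cost]


@dataclass
class RunResult:
    """Everything produced by one consensus run."""

    solution: ConsensusSolution
    cost_report: CostReport
    phase1_maps: list[MapSolution]
    filtered_maps: list[MapSolution]
    conflicts: list[ConflictPair]
    regions: list[ConflictRegion]
    region_solutions: list
    pre_correct_log: list[dict]
    filter_log: list[list[dict]]
    stability: list[StabilityReport | None]
    weights: list[float]
    shared_markers: set[str]
    ges_info: dict | None
    excluded_datasets: list[int]


def compute_weights(
    problem: ConsensusProblem,
    mode: str = "equal",
    phase1_lengths_cM: list[float] | None = None,
) -> list[float]:
    """Dataset weights: all ones, or 1/L_i from the phase-1 map lengths
    (down-weighting noise-inflated datasets)."""
    if mode == "equal":
        return [1.0] * problem.n_datasets
    if mode == "inverse_length":
        if phase1_lengths_cM is None:
            raise ValidationError("inverse_length weights need phase-1 lengths")
        if any(L <= 0 for L in phase1_lengths_cM):
            raise ValidationError("zero-length map; cannot weight by 1/L")
        return [1.0 / L for L in phase1_lengths_cM]
    raise ValidationError(f"unknown weights mode {mode!r}")


# ---------------------------------------------------------------------------
# merging conflict-free maps into one shared order


def merge_shared_orders(
    maps: list[MapSolution], shared: set[str]
) -> SharedOrder:
    """Topologically merge the (conflict-free) shared projections of all
    maps into one total order; lexicographic tie-break for determinism."""
    g = nx.DiGraph()
    g.add_nodes_from(m for sol in maps for m in sol.order if m in shared)
    for sol in maps:
        proj = [m for m in sol.order if m in shared]
        for a, b in itertools.combinations(proj, 2):
            g.add_edge(a, b)
    indeg = dict(g.in_degree())
    heap = [m for m, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    out = []
    while heap:
        m = heapq.heappop(heap)
        out.append(m)
        for _, b in g.out_edges(m):
            indeg[b] -= 1
            if indeg[b] == 0:
                heapq.heappush(heap, b)
    if len(out) != g.number_of_nodes():
        raise ConsmapError("shared orders contain an unresolved cycle")
    return SharedOrder(tuple(out))


def _cycles_to_pairs(
    cycles: list[list[str]], maps: list[MapSolution]
) -> list[ConflictPair]:
    """Represent higher-order conflict cycles as pseudo pairwise conflicts
    so the region machinery absorbs their markers."""
    marker_sets = [set(sol.order) for sol in maps]
    out = []
    for cyc in cycles:
        for a, b in itertools.combinations(cyc, 2):
            ids = frozenset(
                i for i, ms in enumerate(marker_sets) if a in ms and b in ms
            )
            if len(ids) >= 2:
                out.append(ConflictPair(*sorted((a, b)), dataset_ids=ids))
    return out


def _stitch(
    maps: list[MapSolution],
    rf_matrices: list[RFMatrix],
    region: ConflictRegion,
    region_solution,
) -> list[MapSolution]:
    out = list(maps)
    for i, (lo, hi) in region.windows.items():
        order = list(maps[i].order)
        repl = region_solution.per_dataset_orders[i]
        if sorted(order[lo : hi + 1]) != sorted(repl):
            raise ConsmapError(
                f"region stitch mismatch in dataset {i}: "
                f"{sorted(order[lo:hi+1])} vs {sorted(repl)}"
            )
        order[lo : hi + 1] = repl
        out[i] = map_length(order, rf_matrices[i])
    return out


def _effective_problem(
    problem: ConsensusProblem,
    maps: list[MapSolution],
    weights: list[float],
) -> ConsensusProblem:
    """Problem restricted to the markers surviving phase-1 filtering."""
    datasets, rfms = [], []
    for ds, rfm, sol in zip(problem.datasets, problem.rf_matrices, maps):
        keep = [m for m in rfm.markers if m in set(sol.order)]
        idx_g = [ds.marker_index(m) for m in keep]
        datasets.append(
            Dataset(ds.id, ds.cross_type, keep, ds.genotypes[idx_g])
        )
        idx = [rfm.index(m) for m in keep]
        rfms.append(
            RFMatrix(
                keep,
                rfm.rf[np.ix_(idx, idx)],
                np.asarray(rfm.n_informative)[np.ix_(idx, idx)],
            )
        )
    return ConsensusProblem(datasets, rfms, list(weights))


def run_consensus(
    problem: ConsensusProblem,
    config: PipelineConfig | None = None,
    method: str = "both",
) -> RunResult:
    """Run the full two-phase analysis.

    ``method``: ``"local"`` resolves delineated conflict regions only,
    ``"global"`` runs the whole-chromosome GES, ``"both"`` (default) runs
    the local analysis and polishes its result globally, keeping the
    better solution.
    """
    if method not in ("local", "global", "both"):
        raise ValidationError(f"unknown method {method!r}")
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)

    # ---- phase 1: independent ordering, stability, filtering ----------
    phase1_maps: list[MapSolution] = []
    stability: list[StabilityReport | None] = []
    filter_log: list[list[dict]] = []
    filtered: list[MapSolution] = []
    for ds, rfm in zip(problem.datasets, problem.rf_matrices):
        sol = order_single(rfm, solver=config.phase1_solver, rng=rng)
        phase1_maps.append(sol)
        rep = None
        if config.jackknife_replicates > 0:
            rep = jackknife_stability(
                ds,
                sol,
                n_replicates=config.jackknife_replicates,
                drop_fraction=config.drop_fraction,
                rng=rng,
                solver=config.phase1_solver,
            )
        stability.append(rep)

    shared = problem.shared_markers
    for ds, rfm, sol, rep in zip(
        problem.datasets, problem.rf_matrices, phase1_maps, stability
    ):
        if config.skeleton_filtering:
            fsol, log = skeleton_filter(
                ds,
                sol,
                rep,
                rfm,
                consensus_mode=True,
                shared_markers=shared,
                stability_threshold=config.stability_threshold,
            )
        else:
            fsol, log = sol, []
        filtered.append(fsol)
        filter_log.append(log)

    # filtering may demote shared markers present in only one map now
    counts: dict[str, int] = {}
    for sol in filtered:
        for m in sol.order:
            counts[m] = counts.get(m, 0) + 1
    shared_eff = {m for m, c in counts.items() if c >= 2}

    excluded = [
        ds.id
        for ds, sol in zip(problem.datasets, filtered)
        if len([m for m in sol.order if m in shared_eff]) < 2
    ]
    if excluded:
        warnings.warn(
            f"datasets {excluded} have <2 shared markers; they keep their "
            "phase-1 maps and do not constrain the consensus",
            stacklevel=2,
        )

    L_ind_cM = [sol.length_cM for sol in filtered]
    weights = compute_weights(
        problem,
        config.weights_mode,
        phase1_lengths_cM=L_ind_cM,
    )

    # ---- phase 2 -------------------------------------------------------
    maps = orient_maps(filtered, shared_eff, reference=0)
    maps, pc_log = pre_correct(
        maps,
        problem.rf_matrices,
        shared_eff,
        gap_threshold=config.gap_threshold,
        length_tolerance=config.pre_correct_tolerance,
    )

    active = [i for i in range(len(maps)) if i not in set(excluded)]
    active_maps = [maps[i] for i in active]
    conflicts = (
        detect_conflicts(active_maps, shared_eff) if len(active_maps) >= 2 else []
    )
    # re-index dataset ids in conflicts back to the full problem
    conflicts = [
        ConflictPair(
            cp.marker_a,
            cp.marker_b,
            frozenset(active[i] for i in cp.dataset_ids),
        )
        for cp in conflicts
    ]
    cycles = precedence_cycles(active_maps, shared_eff) if len(active_maps) >= 2 else []
    all_pairs = conflicts + _cycles_to_pairs(cycles, maps)

    regions: list[ConflictRegion] = []
    region_solutions: list = []
    if method in ("local", "both") and all_pairs:
        regions = delineate_regions(maps, all_pairs, shared_eff)
        for region in regions:
            est = estimate_complexity(
                region,
                k_plus_n_cap=min(15, config.exact_k_max + config.exact_n_max),
                single_cap=11,
            )
            use_exact = (
                est.feasible
                and est.k <= config.exact_k_max
                and all(n <= config.exact_n_max for n in est.n_by_dataset.values())
            )
            if use_exact:
                tables = build_insertion_tables(region, problem.rf_matrices)
                rsol = solve_region(region, tables, weights, maps)
            else:
                rsol = solve_region_ges(
                    region,
                    problem.rf_matrices,
                    weights,
                    params=config.ges,
                    rng=rng,
                )
            region_solutions.append(rsol)
            maps = _stitch(maps, problem.rf_matrices, region, rsol)

    ges_info = None
    solution: ConsensusSolution | None = None
    eff_problem = _effective_problem(problem, maps, weights)

    if method in ("local", "both"):
        try:
            g = merge_shared_orders(
                [maps[i] for i in active], shared_eff
            )
        except ConsmapError:
            g = None
        if g is not None:
            solution = ConsensusSolution(g, maps, list(weights))

    if method in ("global", "both") or solution is None:
        g_star = solution.shared_order if solution is not None else None
        ges_solution, ges_info = ges_consensus(
            eff_problem, g_star=g_star, params=config.ges, rng=rng
        )
        if solution is None or ges_solution.S_total < solution.S_total - 1e-12:
            solution = ges_solution

    if not conflict_free(solution):  # defensive; should hold by construction
        raise ConsmapError("pipeline produced a conflicting solution")

    cost_report = _cost_report(
        filtered, solution.per_dataset_maps, config.high_cost_threshold_cM
    )
    return RunResult(
        solution=solution,
        cost_report=cost_report,
        phase1_maps=phase1_maps,
        filtered_maps=filtered,
        conflicts=conflicts,
        regions=regions,
        region_solutions=region_solutions,
        pre_correct_log=pc_log,
        filter_log=filter_log,
        stability=stability,
        weights=weights,
        shared_markers=shared_eff,
        ges_info=ges_info,
        excluded_datasets=excluded,
    )


def _incident_edge_sums(sol: MapSolution) -> dict[str, float]:
    out = {m: 0.0 for m in sol.order}
    for (a, b), r in zip(zip(sol.order[:-1], sol.order[1:]), sol.adjacent_rf):
        out[a] += r
        out[b] += r
    return out


def _cost_report(
    before: list[MapSolution],
    after: list[MapSolution],
    threshold_cM: float,
) -> CostReport:
    per = []
    for i, (b, a) in enumerate(zip(before, after)):
        delta = a.length_cM - b.length_cM
        sb = _incident_edge_sums(b)
        sa = _incident_edge_sums(a)
        attribution = {
            m: 100.0 * (sa.get(m, 0.0) - sb.get(m, 0.0)) / 2.0
            for m in set(sb) | set(sa)
        }
        per.append(
            DatasetCost(
                dataset_id=i,
                L_ind_cM=b.length_cM,
                L_cons_cM=a.length_cM,
                delta_cM=delta,
                attribution_cM=attribution,
                high_cost=delta > threshold_cM,
            )
        )
    return CostReport(per, threshold_cM)


# ---------------------------------------------------------------------------
# marker-removal proposals


def _drop_marker_from_dataset(
    problem: ConsensusProblem, dataset_id: int, markers: tuple[str, ...]
) -> ConsensusProblem:
    datasets = list(problem.datasets)
    rfms = list(problem.rf_matrices)
    ds, rfm = datasets[dataset_id], rfms[dataset_id]
    keep = [m for m in ds.markers if m not in markers]
    idx_g = [ds.marker_index(m) for m in keep]
    datasets[dataset_id] = Dataset(ds.id, ds.cross_type, keep, ds.genotypes[idx_g])
    keep_rf = [m for m in rfm.markers if m not in markers]
    idx = [rfm.index(m) for m in keep_rf]
    rfms[dataset_id] = RFMatrix(
        keep_rf,
        rfm.rf[np.ix_(idx, idx)],
        np.asarray(rfm.n_informative)[np.ix_(idx, idx)],
    )
    return ConsensusProblem(datasets, rfms, list(problem.weights))


def suggest_removals(
    problem: ConsensusProblem,
    result: RunResult,
    config: PipelineConfig | None = None,
    cost_threshold_cM: float | None = None,
    max_candidates: int = 4,
    method: str = "local",
) -> list[dict]:
    """Ranked marker-removal proposals for datasets whose cost of consensus
    exceeds the threshold.

    For each high-cost dataset, the markers with the largest cost
    attribution are provisionally removed (one at a time; the top pair
    jointly when no single removal suffices) and the consensus re-run;
    proposals are ranked by the achieved reduction of that dataset's cost.
    Nothing is applied automatically.
    """
    config = config or PipelineConfig()
    thr = (
        cost_threshold_cM
        if cost_threshold_cM is not None
        else config.high_cost_threshold_cM
    )
    proposals = []
    for dc in result.cost_report.per_dataset:
        if dc.delta_cM <= thr:
            continue
        cands = sorted(
            (m for m, v in dc.attribution_cM.items() if v > 0),
            key=lambda m: -dc.attribution_cM[m],
        )[:max_candidates]
        singles = []
        for m in cands:
            trial = _drop_marker_from_dataset(problem, dc.dataset_id, (m,))
            res = run_consensus(trial, config, method=method)
            new_delta = res.cost_report.per_dataset[dc.dataset_id].delta_cM
            singles.append(
                {
                    "dataset_id": dc.dataset_id,
                    "markers": (m,),
                    "delta_before_cM": dc.delta_cM,
                    "delta_after_cM": new_delta,
                    "reduction_cM": dc.delta_cM - new_delta,
                }
            )
        singles.sort(key=lambda p: -p["reduction_cM"])
        proposals.extend(singles)
        resolved = any(p["delta_after_cM"] <= thr for p in singles)
        if not resolved and len(cands) >= 2:
            pair = tuple(cands[:2])
            trial = _drop_marker_from_dataset(problem, dc.dataset_id, pair)
            res = run_consensus(trial, config, method=method)
            new_delta = res.cost_report.per_dataset[dc.dataset_id].delta_cM
            proposals.append(
                {
                    "dataset_id": dc.dataset_id,
                    "markers": pair,
                    "delta_before_cM": dc.delta_cM,
                    "delta_after_cM": new_delta,
                    "reduction_cM": dc.delta_cM - new_delta,
                }
            )
    proposals.sort(key=lambda p: -p["reduction_cM"])
    return proposals


# ---------------------------------------------------------------------------
# scoring against simulation ground truth


def _neighbor_sets(order) -> dict[str, frozenset]:
    order = list(order)
    out = {}
    for i, m in enumerate(order):
        nb = []
        if i > 0:
            nb.append(order[i - 1])
        if i + 1 < len(order):
            nb.append(order[i + 1])
        out[m] = frozenset(nb)
    return out


def order_violations(order, true_order) -> int:
    """Number of markers (common to both orders) whose immediate
    neighbourhood differs from the true order, after orientation
    alignment and restriction to the common marker set."""
    common = set(order) & set(true_order)
    o = [m for m in order if m in common]
    t = [m for m in true_order if m in common]
    o = align_orientation(o, t)
    nb_o = _neighbor_sets(o)
    nb_t = _neighbor_sets(t)
    return sum(1 for m in common if nb_o[m] != nb_t[m])


def recovery_coefficient(shared_order, true_shared_order) -> float:
    """Fraction of shared markers whose neighbourhoods in the consensus
    order match the true order (1.0 = perfect recovery; reversal-safe)."""
    seq = (
        shared_order.sequence
        if isinstance(shared_order, SharedOrder)
        else tuple(shared_order)
    )
    common = set(seq) & set(true_shared_order)
    if not common:
        raise ValidationError("no shared markers in common with ground truth")
    bad = order_violations(seq, true_shared_order)
    return 1.0 - bad / len(common)


# ---------------------------------------------------------------------------
# integral map


def build_integral_map(
    solution: ConsensusSolution, problem: ConsensusProblem | None = None
) -> nx.DiGraph:
    """Build the integral map: a DAG over all markers.

    The consensus shared order forms the backbone; each dataset's unique
    markers appear as chains between their flanking shared anchors, with
    per-dataset edge distances (attributes ``d{i}``, in cM).  When two or
    more datasets place unique markers between the same anchors with no
    cross-dataset order information, their chains stay as parallel
    branches sharing a ``loop`` id — they are never forcibly interleaved
    and distances are never averaged across datasets.
    """
    if not conflict_free(solution):
        raise ValidationError("integral map requires a conflict-free solution")
    g = solution.shared_order
    shared = set(g.sequence)
    G = nx.DiGraph()
    for m in g.sequence:
        G.add_node(m, shared=True)

    # segments per anchor pair: (a, b) -> list of (dataset, [uniques], dists)
    segments: dict[tuple, list[tuple[int, list[str], list[float]]]] = {}
    for ds_i, sol in enumerate(solution.per_dataset_maps):
        order = align_orientation(sol.order, list(g.sequence))
        adj = sol.adjacent_rf if list(order) == list(sol.order) else sol.adjacent_rf[::-1]
        anchor_pos = [p for p, m in enumerate(order) if m in shared]
        bounds = [-1] + anchor_pos + [len(order)]
        for j in range(len(bounds) - 1):
            lo, hi = bounds[j], bounds[j + 1]
            a = order[lo] if lo >= 0 else None
            b = order[hi] if hi < len(order) else None
            seg = order[lo + 1 : hi]
            dists = [100.0 * adj[p] for p in range(max(lo, 0), hi if hi < len(order) else len(order) - 1)]
            if a is None and b is None:
                continue
            segments.setdefault((a, b), []).append((ds_i, seg, dists))

    loop_counter = 0
    for (a, b), branches in segments.items():
        with_uniques = [br for br in branches if br[1]]
        loop_id = -1
        if len(with_uniques) >= 2:
            loop_id = loop_counter
            loop_counter += 1
        for ds_i, seg, dists in branches:
            chain = ([a] if a is not None else []) + seg + ([b] if b is not None else [])
            for u in seg:
                G.add_node(u, shared=False, dataset=ds_i)
            for p, (x, y) in enumerate(zip(chain[:-1], chain[1:])):
                if not G.has_edge(x, y):
                    G.add_edge(x, y, loop=-1)
                d = dists[p] if p < len(dists) else None
                if d is not None:
                    G[x][y][f"d{ds_i}"] = float(d)
                if loop_id >= 0 and seg:
                    G[x][y]["loop"] = loop_id

    # backbone continuity for consecutive shared markers never co-observed
    for a, b in zip(g.sequence[:-1], g.sequence[1:]):
        if not nx.has_path(G, a, b):
            G.add_edge(a, b, loop=-1)

    if not nx.is_directed_acyclic_graph(G):
        raise ConsmapError("integral map is not acyclic")
    return G
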