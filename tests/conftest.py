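"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from consmap.core import MapSolution, RFMatrix
from consmap.simulate import haldane


def map_consistent_rf(
    positions_cM: np.ndarray, markers: list[str] | None = None
) -> RFMatrix:
    """RF matrix derived from true cM positions via Haldane (metric,
    triangle-consistent)."""
    positions_cM = np.asarray(positions_cM, dtype=float)
    m = len(positions_cM)
    markers = markers or [f"m{i + 1}" for i in range(m)]
    d = np.abs(positions_cM[:, None] - positions_cM[None, :])
    rf = np.asarray(haldane(d))
    np.fill_diagonal(rf, 0.0)
    n = np.full((m, m), 1000, dtype=int)
    np.fill_diagonal(n, 0)
    return RFMatrix(markers, rf, n)


def random_rf(m: int, rng: np.random.Generator, jitter: float = 0.0) -> RFMatrix:
    """Random map-consistent RF matrix, optionally with symmetric noise."""
    pos = np.concatenate(([0.0], np.cumsum(rng.uniform(1, 15, m - 1))))
    rfm = map_consistent_rf(pos)
    if jitter > 0:
        noise = rng.normal(0, jitter, (m, m))
        noise = (noise + noise.T) / 2
        rf = np.clip(rfm.rf + noise, 0.0, 0.5)
        np.fill_diagonal(rf, 0.0)
        rfm = RFMatrix(rfm.markers, rf, rfm.n_informative)
    return rfm


def arbitrary_rf(m: int, rng: np.random.Generator) -> RFMatrix:
    """Fully random symmetric RF matrix (no metric structure)."""
    rf = rng.uniform(0.0, 0.5, (m, m))
    rf = (rf + rf.T) / 2
    np.fill_diagonal(rf, 0.0)
    n = np.full((m, m), 1000, dtype=int)
    np.fill_diagonal(n, 0)
    return RFMatrix([f"m{i + 1}" for i in range(m)], rf, n)


def path_cost(order: list[str], rfm: RFMatrix) -> float:
    """Independent summation oracle for map length."""
    return sum(rfm.dist(a, b) for a, b in zip(order[:-1], order[1:]))


def brute_force_best_path(rfm: RFMatrix) -> tuple[float, tuple[str, ...]]:
    """Exhaustive minimum open path over all permutations."""
    best = (np.inf, None)
    for perm in itertools.permutations(rfm.markers):
        c = path_cost(list(perm), rfm)
        if c < best[0] - 1e-15:
            best = (c, perm)
    return best


def conflict_free_oracle(orders: list[list[str]], shared: set[str]) -> bool:
    """Quadratic oracle: every pair of maps has an orientation of the
    second with zero discordant shared pairs against the first."""
    for oi, oj in itertools.combinations(orders, 2):
        common = [m for m in oi if m in set(oj) and m in shared]
        if len(common) < 2:
            continue
        pos_i = {m: p for p, m in enumerate(oi)}
        ok = False
        for cand in (oj, oj[::-1]):
            pos_j = {m: p for p, m in enumerate(cand)}
            bad = sum(
                1
                for a, b in itertools.combinations(common, 2)
                if (pos_i[a] - pos_i[b]) * (pos_j[a] - pos_j[b]) < 0
            )
            if bad == 0:
                ok = True
                break
        if not ok:
            return False
    return True


def make_map(order: list[str], rfm: RFMatrix | None = None) -> MapSolution:
    """MapSolution from a plain order (zero distances when no rf given)."""
    if rfm is None:
        return MapSolution(order, [0.0] * (len(order) - 1))
    return MapSolution(
        order, [rfm.dist(a, b) for a, b in zip(order[:-1], order[1:])]
    )


def embeddings(content: list[str], anchors: list[str]):
    """All permutations of ``content`` preserving the order of ``anchors``
    as a subsequence."""
    anchor_pos = {m: i for i, m in enumerate(anchors)}
    for perm in itertools.permutations(content):
        seq = [anchor_pos[m] for m in perm if m in anchor_pos]
        if seq == sorted(seq):
            yield list(perm)


def region_bruteforce(region, rf_matrices, weights):
    """Exhaustive constrained enumeration over a conflict region: every
    shared suborder x every per-dataset interleaving of unique markers."""
    best_total, best_orders = np.inf, None
    for perm in itertools.permutations(region.shared):
        total = 0.0
        orders = {}
        feasible = True
        for i, (lo, hi) in region.windows.items():
            rfm = rf_matrices[i]
            present = set(rfm.markers)
            proj = [m for m in perm if m in present]
            uniques = region.unique_by_dataset.get(i, [])
            content = proj + list(uniques)
            left, right = region.flanks[i]
            best_ds = np.inf
            best_o = None
            for cand in embeddings(content, proj):
                full = ([left] if left else []) + cand + ([right] if right else [])
                c = path_cost(full, rfm)
                if c < best_ds - 1e-15:
                    best_ds, best_o = c, cand
            if best_o is None:
                feasible = False
                break
            total += weights[i] * best_ds
            orders[i] = best_o
        if feasible and total < best_total - 1e-12:
            best_total, best_orders = total, orders
    return best_total, best_orders


def random_region_instance(rng, n_datasets=2, k=3, n_per=1, drop_shared=False):
    """A synthetic conflict region plus per-dataset RF matrices."""
    from consmap.conflicts import ConflictRegion

    shared = [f"s{j + 1}" for j in range(k)]
    rf_matrices, windows, uniques_by, flanks = [], {}, {}, {}
    for i in range(n_datasets):
        present = list(shared)
        if drop_shared and k > 2 and rng.random() < 0.5:
            present = [m for m in present if m != shared[int(rng.integers(k))]]
            if len(present) < 1:
                present = list(shared)
        uniq = [f"u{i}_{j + 1}" for j in range(n_per)]
        content = list(rng.permutation(present + uniq))
        markers = ["L"] + content + ["R"]
        rf_matrices.append(arbitrary_rf_named(markers, rng))
        windows[i] = (1, len(markers) - 2)
        uniques_by[i] = uniq
        flanks[i] = ("L", "R")
    region = ConflictRegion(shared, windows, uniques_by, flanks)
    return region, rf_matrices


def arbitrary_rf_named(markers: list[str], rng: np.random.Generator) -> RFMatrix:
    m = len(markers)
    rf = rng.uniform(0.01, 0.5, (m, m))
    rf = (rf + rf.T) / 2
    np.fill_diagonal(rf, 0.0)
    n = np.full((m, m), 1000, dtype=int)
    np.fill_diagonal(n, 0)
    return RFMatrix(markers, rf, n)


def consensus_bruteforce(problem):
    """Global exhaustive optimum of the synchronized ordering criterion."""
    shared = sorted(problem.shared_markers)
    best = np.inf
    for perm in itertools.permutations(shared):
        total = 0.0
        for rfm, w in zip(problem.rf_matrices, problem.weights):
            present = set(rfm.markers)
            proj = [m for m in perm if m in present]
            content = list(rfm.markers)
            best_ds = min(
                path_cost(cand, rfm) for cand in embeddings(content, proj)
            )
            total += w * best_ds
        best = min(best, total)
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
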