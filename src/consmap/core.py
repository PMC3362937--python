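"""Core data containers and optimization criteria for consensus mapping.

The consensus mapping problem takes several mapping populations (datasets)
genotyped on partially overlapping marker sets for the same chromosome.  A
marker present in two or more datasets is *shared*; one present in a single
dataset is *unique*.  The objective is a common order of the shared markers
such that the weighted sum of per-dataset map lengths, with unique markers
placed optimally around the shared anchors, is minimal:

    S(g) = sum_i  w_i * min_{u in U(i, g(i))} S_i(g(i), u)

where g is an order of the shared markers, g(i) its restriction to dataset i,
U(i, g(i)) the orders of dataset i's markers embedding g(i), and S_i the sum
of recombination fractions between adjacent markers along the map.  The
cheaper *skeleton* criterion S_shared(g) = sum_i w_i * S_i(g(i)) evaluates g
on the shared markers alone and is used to screen candidate orders.

Lengths are kept in criterion units (sum of recombination fractions, i.e.
Morgans without a mapping function); reporting multiplies by 100 for cM.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    ConstraintViolationError,
    IdentifierError,
    ValidationError,
)

__all__ = [
    "CrossType",
    "MISSING",
    "CODE_TO_INT",
    "INT_TO_CODE",
    "Dataset",
    "RFMatrix",
    "MapSolution",
    "SharedOrder",
    "ConsensusProblem",
    "ConsensusSolution",
    "map_length",
    "criterion_S",
    "skeleton_criterion",
    "conflict_free",
    "discordant_pairs",
    "align_orientation",
    "is_subsequence",
]


class CrossType(str, enum.Enum):
    """Mapping population design."""

    F2 = "F2"
    BC = "BC"
    RIL = "RIL"


#: integer genotype codes used in :attr:`Dataset.genotypes`
MISSING = -1
CODE_TO_INT = {"A": 0, "H": 1, "B": 2, "-": MISSING, "U": MISSING}
INT_TO_CODE = {0: "A", 1: "H", 2: "B", MISSING: "-"}

_ALLOWED_CODES = {
    CrossType.F2: {0, 1, 2, MISSING},
    CrossType.BC: {0, 1, MISSING},
    CrossType.RIL: {0, 2, MISSING},
}


@dataclass
class Dataset:
    """One mapping population: genotype matrix plus cross-type metadata.

    Parameters
    ----------
    id : int
        Index of the population within a consensus problem.
    cross_type : CrossType
        F2 intercross, backcross (BC) or recombinant inbred lines (RIL).
    markers : sequence of str
        Marker names, one per genotype row.  Shared markers are recognised
        by identical names across datasets.
    genotypes : ndarray of shape (n_markers, n_individuals)
        Integer codes 0 = A homozygote, 1 = heterozygote, 2 = B homozygote,
        -1 = missing.  BC data may not contain code 2; RIL data (taken to
        fixation) may not contain code 1.
    """

    id: int
    cross_type: CrossType
    markers: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.cross_type = CrossType(self.cross_type)
        self.markers = list(self.markers)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D matrix")
        if len(self.markers) != self.genotypes.shape[0]:
            raise ValidationError(
                f"{len(self.markers)} marker names for "
                f"{self.genotypes.shape[0]} genotype rows"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError("duplicate marker names within a dataset")
        if any(not m for m in self.markers):
            raise ValidationError("empty marker name")
        seen = set(np.unique(self.genotypes).tolist())
        allowed = _ALLOWED_CODES[self.cross_type]
        if not seen <= allowed:
            raise ValidationError(
                f"genotype codes {sorted(seen - allowed)} not allowed for "
                f"{self.cross_type.value} data"
            )

    @property
    def sample_size(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, name: str) -> int:
        try:
            return self.markers.index(name)
        except ValueError:
            raise IdentifierError(name) from None


@dataclass
class RFMatrix:
    """Pairwise recombination-fraction estimates for one dataset.

    ``rf`` is symmetric with zero diagonal and entries in [0, 0.5];
    ``n_informative`` counts the individuals informative for each pair.
    ``unreliable`` flags pairs whose direct estimate rested on too few
    informative individuals and was imputed (see :mod:`consmap.twopoint`).
    """

    markers: list[str]
    rf: np.ndarray
    n_informative: np.ndarray
    unreliable: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.markers = list(self.markers)
        self.rf = np.asarray(self.rf, dtype=float)
        self.n_informative = np.asarray(self.n_informative)
        m = len(self.markers)
        if self.rf.shape != (m, m):
            raise ValidationError("rf matrix shape does not match markers")
        if not np.allclose(self.rf, self.rf.T):
            raise ValidationError("rf matrix must be symmetric")
        if np.any(np.diag(self.rf) != 0):
            raise ValidationError("rf diagonal must be zero")
        if np.any(self.rf < 0) or np.any(self.rf > 0.5 + 1e-12):
            raise ValidationError("rf entries must lie in [0, 0.5]")
        if self.unreliable is None:
            self.unreliable = np.zeros((m, m), dtype=bool)
        self._index = {name: i for i, name in enumerate(self.markers)}

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise IdentifierError(name) from None

    def submatrix(self, order: Sequence[str]) -> np.ndarray:
        """Return rf restricted to ``order`` (in that order)."""
        idx = [self.index(m) for m in order]
        return self.rf[np.ix_(idx, idx)]

    def dist(self, a: str, b: str) -> float:
        return float(self.rf[self.index(a), self.index(b)])


@dataclass
class MapSolution:
    """An ordered marker sequence with adjacent distances.

    ``length_S`` is the criterion value (sum of adjacent recombination
    fractions); ``length_cM`` is the 100x reporting scale.
    """

    order: list[str]
    adjacent_rf: list[float]

    def __post_init__(self) -> None:
        self.order = list(self.order)
        self.adjacent_rf = [float(x) for x in self.adjacent_rf]
        if len(set(self.order)) != len(self.order):
            raise ValidationError("duplicate markers in map order")
        if len(self.adjacent_rf) != max(len(self.order) - 1, 0):
            raise ValidationError("adjacent_rf length must be |order| - 1")

    @property
    def length_S(self) -> float:
        return float(sum(self.adjacent_rf))

    @property
    def length_cM(self) -> float:
        return 100.0 * self.length_S

    @property
    def positions_cM(self) -> list[float]:
        """Cumulative positions in cM from the left end."""
        return [100.0 * p for p in np.concatenate(([0.0], np.cumsum(self.adjacent_rf)))]

    def reversed(self) -> "MapSolution":
        return MapSolution(self.order[::-1], self.adjacent_rf[::-1])

    def restrict(self, keep: Iterable[str]) -> list[str]:
        keep = set(keep)
        return [m for m in self.order if m in keep]


@dataclass
class SharedOrder:
    """A candidate order g of the shared-marker set R.

    A shared order and its full reversal are equivalent solutions; use
    :func:`align_orientation` before comparing two orders.
    """

    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        self.sequence = tuple(self.sequence)
        if len(set(self.sequence)) != len(self.sequence):
            raise ValidationError("duplicate markers in shared order")

    def projection(self, dataset_markers: Iterable[str]) -> tuple[str, ...]:
        """g(i): the subsequence restricted to markers of one dataset."""
        present = set(dataset_markers)
        return tuple(m for m in self.sequence if m in present)

    def reversed(self) -> "SharedOrder":
        return SharedOrder(self.sequence[::-1])

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ConsensusProblem:
    """Datasets with their RF matrices, weights, and the shared registry."""

    datasets: list[Dataset]
    rf_matrices: list[RFMatrix]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.datasets) != len(self.rf_matrices):
            raise ValidationError("one RFMatrix per dataset required")
        if self.weights is None:
            self.weights = [1.0] * len(self.datasets)
        self.weights = [float(w) for w in self.weights]
        if len(self.weights) != len(self.datasets):
            raise ValidationError("one weight per dataset required")
        if any(w <= 0 for w in self.weights):
            raise ValidationError("weights must be positive")

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def shared_registry(self) -> dict[str, set[int]]:
        """Map from shared marker name to the ids of datasets containing it."""
        presence: dict[str, set[int]] = {}
        for ds in self.datasets:
            for m in ds.markers:
                presence.setdefault(m, set()).add(ds.id)
        return {m: ids for m, ids in presence.items() if len(ids) >= 2}

    @property
    def shared_markers(self) -> set[str]:
        return set(self.shared_registry)

    def unique_markers(self, dataset: Dataset) -> list[str]:
        shared = self.shared_markers
        return [m for m in dataset.markers if m not in shared]


@dataclass
class ConsensusSolution:
    """A consensus shared order with per-dataset maps embedding it."""

    shared_order: SharedOrder
    per_dataset_maps: list[MapSolution]
    weights: list[float]

    @property
    def S_total(self) -> float:
        return float(
            sum(w * m.length_S for w, m in zip(self.weights, self.per_dataset_maps))
        )


# ---------------------------------------------------------------------------
# criteria


def map_length(order: Sequence[str], rf: RFMatrix) -> MapSolution:
    """Build a :class:`MapSolution` for ``order`` under ``rf``.

    The map length is the sum of recombination fractions over consecutive
    marker pairs; it is invariant under reversal of the order.
    """
    order = list(order)
    if len(set(order)) != len(order):
        raise ValidationError("duplicate markers in order")
    sub = rf.submatrix(order)  # raises IdentifierError for unknown markers
    adj = list(np.diag(sub, k=1)) if len(order) > 1 else []
    return MapSolution(order, adj)


def is_subsequence(sub: Sequence[str], seq: Sequence[str]) -> bool:
    it = iter(seq)
    return all(any(x == y for y in it) for x in sub)


def criterion_S(
    g: SharedOrder,
    problem: ConsensusProblem,
    per_dataset_orders: Sequence[Sequence[str]],
) -> float:
    """Evaluate the main criterion S(g) = sum_i w_i S_i for given full orders.

    Each per-dataset order must embed g(i) (the restriction of ``g`` to that
    dataset's markers) as a subsequence, in either orientation.
    """
    if len(per_dataset_orders) != problem.n_datasets:
        raise ValidationError("one order per dataset required")
    total = 0.0
    for ds, rfm, w, order in zip(
        problem.datasets, problem.rf_matrices, problem.weights, per_dataset_orders
    ):
        gi = g.projection(ds.markers)
        if not (
            is_subsequence(gi, order) or is_subsequence(gi[::-1], order)
        ):
            raise ConstraintViolationError(
                f"dataset {ds.id}: order does not embed the shared suborder"
            )
        total += w * map_length(order, rfm).length_S
    return float(total)


def skeleton_criterion(g: SharedOrder, problem: ConsensusProblem) -> float:
    """S_shared(g) = sum_i w_i * length of g(i) alone, ignoring unique markers."""
    if len(g) == 0:
        raise ValidationError("empty shared order")
    total = 0.0
    for ds, rfm, w in zip(problem.datasets, problem.rf_matrices, problem.weights):
        gi = g.projection(ds.markers)
        if len(gi) >= 2:
            total += w * map_length(gi, rfm).length_S
    return float(total)


# ---------------------------------------------------------------------------
# orientation and conflict checking


def _pair_sign_matrix(order: Sequence[str], common: Sequence[str]) -> np.ndarray:
    pos = {m: i for i, m in enumerate(order)}
    p = np.array([pos[m] for m in common])
    return np.sign(p[:, None] - p[None, :])


def discordant_pairs(
    order_a: Sequence[str], order_b: Sequence[str], common: Iterable[str] | None = None
) -> tuple[int, int]:
    """Count (concordant, discordant) marker pairs between two orders.

    Only markers present in both orders are compared.  No orientation
    alignment is applied here.
    """
    if common is None:
        common = [m for m in order_a if m in set(order_b)]
    common = list(common)
    if len(common) < 2:
        return 0, 0
    sa = _pair_sign_matrix(order_a, common)
    sb = _pair_sign_matrix(order_b, common)
    iu = np.triu_indices(len(common), k=1)
    agree = int(np.sum(sa[iu] == sb[iu]))
    disagree = int(np.sum(sa[iu] != sb[iu]))
    return agree, disagree


def align_orientation(
    order: Sequence[str], reference: Sequence[str]
) -> list[str]:
    """Return ``order`` or its reversal, whichever is more concordant with
    ``reference`` on their common markers.  Ties keep the input orientation."""
    agree, disagree = discordant_pairs(order, reference)
    if disagree > agree:
        return list(order)[::-1]
    return list(order)


def conflict_free(solution: ConsensusSolution) -> bool:
    """True iff no pair of shared markers appears in opposite relative order
    in any two per-dataset maps, after orientation alignment of each pair."""
    orders = [m.order for m in solution.per_dataset_maps]
    shared = set(solution.shared_order.sequence)
    for i in range(len(orders)):
        oi = [m for m in orders[i] if m in shared]
        for j in range(i + 1, len(orders)):
            oj = [m for m in orders[j] if m in shared]
            oj_aligned = align_orientation(oj, oi)
            _, disagree = discordant_pairs(oi, oj_aligned)
            if disagree > 0:
                return False
    return True
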