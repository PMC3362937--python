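"""Core containers and the optimization criteria."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consmap.core import (
    ConsensusProblem,
    ConsensusSolution,
    CrossType,
    Dataset,
    MapSolution,
    RFMatrix,
    SharedOrder,
    align_orientation,
    conflict_free,
    criterion_S,
    map_length,
    skeleton_criterion,
)
from consmap.exceptions import (
    ConstraintViolationError,
    IdentifierError,
    ValidationError,
)

from .conftest import (
    arbitrary_rf,
    conflict_free_oracle,
    make_map,
    map_consistent_rf,
    path_cost,
    random_rf,
)


def three_marker_rf() -> RFMatrix:
    rf = np.array([[0.0, 0.10, 0.30], [0.10, 0.0, 0.20], [0.30, 0.20, 0.0]])
    n = np.full((3, 3), 100)
    np.fill_diagonal(n, 0)
    return RFMatrix(["a", "b", "c"], rf, n)


class TestMapLength:
    def test_direct_sum_and_cm_scale(self):
        sol = map_length(["a", "b", "c"], three_marker_rf())
        assert sol.length_S == pytest.approx(0.30)
        assert sol.length_cM == pytest.approx(30.0)

    def test_reversal_invariance(self, rng):
        rfm = random_rf(8, rng)
        order = list(rng.permutation(rfm.markers))
        assert map_length(order, rfm).length_S == pytest.approx(
            map_length(order[::-1], rfm).length_S
        )

    def test_matches_summation_oracle(self, rng):
        rfm = arbitrary_rf(8, rng)
        order = list(rng.permutation(rfm.markers))
        assert map_length(order, rfm).length_S == pytest.approx(
            path_cost(order, rfm), abs=1e-12
        )

    def test_unknown_marker_raises(self):
        with pytest.raises(IdentifierError):
            map_length(["a", "zzz"], three_marker_rf())

    def test_duplicate_marker_raises(self):
        with pytest.raises(ValidationError):
            map_length(["a", "a", "b"], three_marker_rf())

    def test_positions_start_at_zero(self):
        sol = map_length(["a", "b", "c"], three_marker_rf())
        assert sol.positions_cM == pytest.approx([0.0, 10.0, 30.0])


class TestValidation:
    def test_rf_matrix_must_be_symmetric(self):
        bad = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(ValidationError):
            RFMatrix(["a", "b"], bad, np.ones((2, 2)))

    def test_rf_entries_bounded(self):
        bad = np.array([[0.0, 0.7], [0.7, 0.0]])
        with pytest.raises(ValidationError):
            RFMatrix(["a", "b"], bad, np.ones((2, 2)))

    def test_dataset_rejects_wrong_codes_for_cross(self):
        with pytest.raises(ValidationError):
            Dataset(0, CrossType.RIL, ["a"], np.array([[0, 1, 2]]))

    def test_dataset_rejects_duplicate_markers(self):
        with pytest.raises(ValidationError):
            Dataset(0, CrossType.BC, ["a", "a"], np.zeros((2, 3)))


def _two_dataset_problem(rng):
    rf1 = random_rf(5, rng)
    rf2 = random_rf(5, rng)
    rf2.markers[4] = "u2"  # one unique marker in each dataset
    rf2._index = {m: i for i, m in enumerate(rf2.markers)}
    rf1.markers[4] = "u1"
    rf1._index = {m: i for i, m in enumerate(rf1.markers)}
    g1 = np.zeros((5, 4), dtype=np.int8)
    g2 = np.zeros((5, 4), dtype=np.int8)
    d1 = Dataset(0, CrossType.BC, rf1.markers, g1)
    d2 = Dataset(1, CrossType.BC, rf2.markers, g2)
    return ConsensusProblem([d1, d2], [rf1, rf2])


class TestCriteria:
    def test_single_dataset_criterion_equals_map_length(self, rng):
        rfm = random_rf(6, rng)
        geno = np.zeros((6, 4), dtype=np.int8)
        ds = Dataset(0, CrossType.BC, rfm.markers, geno)
        # duplicate the dataset so markers count as shared
        ds2 = Dataset(1, CrossType.BC, rfm.markers, geno)
        problem = ConsensusProblem([ds, ds2], [rfm, rfm])
        g = SharedOrder(tuple(rfm.markers))
        order = list(rfm.markers)
        val = criterion_S(g, problem, [order, order])
        assert val == pytest.approx(2 * map_length(order, rfm).length_S)

    def test_criterion_decomposes_per_dataset(self, rng):
        problem = _two_dataset_problem(rng)
        shared = sorted(problem.shared_markers)
        g = SharedOrder(tuple(shared))
        orders = []
        for ds in problem.datasets:
            sh = [m for m in g.sequence if m in ds.markers]
            uniq = [m for m in ds.markers if m not in problem.shared_markers]
            orders.append(sh + uniq)
        total = criterion_S(g, problem, orders)
        manual = sum(
            w * map_length(o, rfm).length_S
            for w, rfm, o in zip(problem.weights, problem.rf_matrices, orders)
        )
        assert total == pytest.approx(manual, abs=1e-12)

    def test_order_violating_embedding_raises(self, rng):
        problem = _two_dataset_problem(rng)
        shared = sorted(problem.shared_markers)
        g = SharedOrder(tuple(shared))
        bad = [shared[1], shared[0]] + [
            m for m in problem.datasets[0].markers if m not in shared
        ] + shared[2:]
        good = [m for m in g.sequence if m in problem.datasets[1].markers] + ["u2"]
        with pytest.raises(ConstraintViolationError):
            criterion_S(g, problem, [bad, good])

    def test_skeleton_equals_criterion_without_uniques(self, rng):
        rfm = random_rf(5, rng)
        geno = np.zeros((5, 4), dtype=np.int8)
        d1 = Dataset(0, CrossType.BC, rfm.markers, geno)
        d2 = Dataset(1, CrossType.BC, rfm.markers, geno)
        problem = ConsensusProblem([d1, d2], [rfm, rfm])
        g = SharedOrder(tuple(rfm.markers))
        orders = [list(g.sequence)] * 2
        assert skeleton_criterion(g, problem) == pytest.approx(
            criterion_S(g, problem, orders)
        )

    def test_skeleton_hand_computed(self):
        rf1 = map_consistent_rf([0.0, 10.0, 30.0], ["a", "b", "c"])
        rf2 = map_consistent_rf([0.0, 5.0, 12.0], ["a", "b", "c"])
        geno = np.zeros((3, 4), dtype=np.int8)
        d1 = Dataset(0, CrossType.BC, ["a", "b", "c"], geno)
        d2 = Dataset(1, CrossType.BC, ["a", "b", "c"], geno)
        problem = ConsensusProblem([d1, d2], [rf1, rf2])
        g = SharedOrder(("a", "b", "c"))
        expected = (rf1.dist("a", "b") + rf1.dist("b", "c")) + (
            rf2.dist("a", "b") + rf2.dist("b", "c")
        )
        assert skeleton_criterion(g, problem) == pytest.approx(expected)

    def test_skeleton_minimal_at_true_order(self, rng):
        """Exhaustive over 3! permutations: the true order has the
        smallest skeleton value on map-consistent matrices."""
        rf1 = map_consistent_rf([0.0, 8.0, 20.0], ["a", "b", "c"])
        rf2 = map_consistent_rf([0.0, 4.0, 9.0], ["a", "b", "c"])
        geno = np.zeros((3, 4), dtype=np.int8)
        d1 = Dataset(0, CrossType.BC, ["a", "b", "c"], geno)
        d2 = Dataset(1, CrossType.BC, ["a", "b", "c"], geno)
        problem = ConsensusProblem([d1, d2], [rf1, rf2])
        values = {
            perm: skeleton_criterion(SharedOrder(perm), problem)
            for perm in itertools.permutations(("a", "b", "c"))
        }
        true_val = values[("a", "b", "c")]
        assert all(
            true_val <= v + 1e-12 for v in values.values()
        )
        # strictly larger for any order that is not the truth or its reversal
        for perm, v in values.items():
            if perm not in {("a", "b", "c"), ("c", "b", "a")}:
                assert v > true_val + 1e-9

    def test_skeleton_raises_on_empty(self, rng):
        problem = _two_dataset_problem(rng)
        with pytest.raises(ValidationError):
            skeleton_criterion(SharedOrder(()), problem)

    def test_skeleton_not_above_full_criterion(self, rng):
        """With triangle-consistent rf, dropping unique markers can only
        shorten each dataset's path."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            rfm = random_rf(7, r)
            geno = np.zeros((7, 4), dtype=np.int8)
            markers1 = list(rfm.markers)
            d1 = Dataset(0, CrossType.BC, markers1, geno)
            d2 = Dataset(1, CrossType.BC, markers1[:5], geno[:5])
            rf2 = random_rf(5, r)
            rf2.markers[:] = markers1[:5]
            rf2._index = {m: i for i, m in enumerate(rf2.markers)}
            problem = ConsensusProblem([d1, d2], [rfm, rf2])
            shared = [m for m in markers1[:5]]
            g = SharedOrder(tuple(shared))
            orders = [
                shared + markers1[5:],
                shared,
            ]
            assert skeleton_criterion(g, problem) <= criterion_S(
                g, problem, orders
            ) + 1e-12


class TestConflictFree:
    def _solution(self, orders, shared):
        maps = [make_map(o) for o in orders]
        return ConsensusSolution(
            SharedOrder(tuple(sorted(shared))), maps, [1.0] * len(maps)
        )

    def test_identical_orders_conflict_free(self):
        orders = [["a", "b", "c", "d"]] * 3
        assert conflict_free(self._solution(orders, {"a", "b", "c", "d"}))

    def test_swapped_pair_conflicts(self):
        orders = [["x", "a", "b", "y"], ["x", "b", "a", "y"]]
        assert not conflict_free(self._solution(orders, {"x", "a", "b", "y"}))

    def test_reversed_map_is_not_a_conflict(self):
        orders = [["a", "b", "c", "d"], ["d", "c", "b", "a"]]
        assert conflict_free(self._solution(orders, {"a", "b", "c", "d"}))

    def test_agrees_with_bruteforce_oracle(self, rng):
        markers = [f"m{i}" for i in range(10)]
        shared = set(markers)
        for _ in range(40):
            orders = []
            base = list(rng.permutation(markers))
            for _ in range(3):
                o = list(base)
                if rng.random() < 0.6:
                    i = int(rng.integers(0, 9))
                    o[i], o[i + 1] = o[i + 1], o[i]
                if rng.random() < 0.5:
                    o = o[::-1]
                orders.append(o)
            sol = self._solution(orders, shared)
            assert conflict_free(sol) == conflict_free_oracle(orders, shared)


class TestOrientation:
    def test_align_keeps_or_reverses(self):
        ref = ["a", "b", "c", "d"]
        assert align_orientation(["d", "c", "b", "a"], ref) == ref
        assert align_orientation(ref, ref) == ref


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(4, 9))
def test_map_length_reversal_property(seed, m):
    """Reversing any order never changes the map length."""
    r = np.random.default_rng(seed)
    rfm = arbitrary_rf(m, r)
    order = list(r.permutation(rfm.markers))
    assert map_length(order, rfm).length_S == pytest.approx(
        map_length(order[::-1], rfm).length_S, abs=1e-12
    )
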