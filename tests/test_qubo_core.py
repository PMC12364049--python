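import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qubofs import (
    FeatureMask,
    QuboMatrix,
    add_cardinality_penalty,
    build_qubo,
    energy,
    energy_path,
    rank_by_contribution,
)
from qubofs.qubo_core import from_coo_text, to_coo_text
from qubofs.errors import DataError, InvalidParameterError


def brute_force_min(Q):
    """Independent oracle: enumerate every mask with explicit summation."""
    n = Q.n_features
    best = (np.inf, None)
    for bits in itertools.product([0, 1], repeat=n):
        e = sum(Q.q[i, i] * bits[i] for i in range(n))
        e += sum(
            Q.q[i, j] * bits[i] * bits[j]
            for i in range(n)
            for j in range(i + 1, n)
        )
        if e < best[0]:
            best = (e, bits)
    return best


class TestBuildQubo:
    def test_importance_only_limit(self):
        I = np.array([0.3, 0.1, 0.2])
        R = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        Q = build_qubo(I, R, alpha=1.0)
        assert np.allclose(np.diag(Q.q), -I)
        assert np.all(np.triu(Q.q, 1) == 0)
        # minimizing selects every positive-importance feature
        _, bits = brute_force_min(Q)
        assert bits == (1, 1, 1)

    def test_redundancy_only_limit(self):
        I = np.array([0.3, 0.1])
        R = np.array([[0, 0.4], [0.4, 0]])
        Q = build_qubo(I, R, alpha=0.0)
        assert np.all(np.diag(Q.q) == 0)
        e, bits = brute_force_min(Q)
        assert bits == (0, 0) and e == 0

    def test_symmetric_pair_folds_into_upper_triangle(self):
        I = np.array([0.4, 0.2])
        R = np.array([[0, 0.1], [0.1, 0]])
        Q = build_qubo(I, R, alpha=0.5)
        assert Q.q[0, 0] == pytest.approx(-0.2)
        assert Q.q[1, 1] == pytest.approx(-0.1)
        assert Q.q[0, 1] == pytest.approx(0.1)
        assert Q.q[1, 0] == 0

    @pytest.mark.parametrize("alpha", [-0.1, 1.5])
    def test_alpha_domain(self, alpha):
        with pytest.raises(InvalidParameterError):
            build_qubo(np.ones(2), np.zeros((2, 2)), alpha)

    def test_dimension_mismatch(self):
        with pytest.raises(DataError):
            build_qubo(np.ones(3), np.zeros((2, 2)), 0.5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    def test_matrix_energy_reproduces_double_sum(self, seed, alpha):
        # E(x) = -alpha sum I_i x_i + (1-alpha) sum_{i != j} R_ij x_i x_j
        rng = np.random.default_rng(seed)
        n = 6
        I = rng.random(n)
        R = np.abs(rng.normal(size=(n, n)))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 0)
        Q = build_qubo(I, R, alpha)
        x = rng.integers(0, 2, n)
        direct = -alpha * np.sum(I * x) + (1 - alpha) * np.sum(
            R * np.outer(x, x)
        )
        assert energy(Q, FeatureMask(x)) == pytest.approx(direct, abs=1e-10)

    def test_homogeneity_preserves_argmin(self):
        rng = np.random.default_rng(11)
        I = rng.random(5)
        R = np.abs(rng.normal(size=(5, 5)))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 0)
        Q1 = build_qubo(I, R, 0.6)
        Q3 = build_qubo(3 * I, 3 * R, 0.6)
        e1, b1 = brute_force_min(Q1)
        e3, b3 = brute_force_min(Q3)
        assert e3 == pytest.approx(3 * e1, abs=1e-10)
        assert b1 == b3


class TestEnergy:
    def test_zero_mask_is_exactly_zero(self, three_var_q):
        assert energy(three_var_q, FeatureMask(np.zeros(3, dtype=int))) == 0.0

    def test_single_bit_reads_the_diagonal(self, three_var_q):
        for i in range(3):
            bits = np.zeros(3, dtype=int)
            bits[i] = 1
            assert energy(three_var_q, FeatureMask(bits)) == three_var_q.q[i, i]

    def test_hand_enumerated_three_variable_case(self, three_var_q):
        assert energy(three_var_q, FeatureMask([1, 1, 0])) == pytest.approx(-1.5)
        e, bits = brute_force_min(three_var_q)
        assert bits == (1, 1, 0) and e == pytest.approx(-1.5)


class TestCardinalityPenalty:
    def test_full_mask_pays_nothing_at_k_equals_n(self):
        rng = np.random.default_rng(0)
        from .conftest import random_qubo

        Q = random_qubo(rng, 5)
        M = 2.0
        Qp = add_cardinality_penalty(Q, k=5, M=M)
        full = FeatureMask(np.ones(5, dtype=int))
        # a satisfied constraint contributes M * 0; only the documented
        # dropped constant -M k^2 offsets the penalized energy
        assert energy(Qp, full) == pytest.approx(
            energy(Q, full) + M * 0 - M * 5**2, abs=1e-10
        )

    def test_zero_matrix_k1_minimizers_are_single_bits(self):
        Q = QuboMatrix(np.zeros((3, 3)))
        Qp = add_cardinality_penalty(Q, k=1, M=1.0)
        energies = {
            bits: energy(Qp, FeatureMask(np.array(bits)))
            for bits in itertools.product([0, 1], repeat=3)
        }
        best = min(energies.values())
        winners = [b for b, e in energies.items() if e == pytest.approx(best)]
        assert sorted(winners) == [(0, 0, 1), (0, 1, 0), (1, 0, 0)]

    def test_penalized_energy_identity(self):
        rng = np.random.default_rng(1)
        from .conftest import random_qubo

        Q = random_qubo(rng, 6)
        M, k = 3.0, 2
        Qp = add_cardinality_penalty(Q, k=k, M=M)
        for _ in range(10):
            bits = rng.integers(0, 2, 6)
            c = bits.sum()
            assert energy(Qp, FeatureMask(bits)) == pytest.approx(
                energy(Q, FeatureMask(bits)) + M * (c - k) ** 2 - M * k**2,
                abs=1e-10,
            )

    def test_default_magnitude_enforces_exact_k(self):
        from qubofs import solve_exhaustive

        rng = np.random.default_rng(2)
        from .conftest import random_qubo

        for _ in range(5):
            Q = random_qubo(rng, 8)
            Qp = add_cardinality_penalty(Q, k=3)
            res = solve_exhaustive(Qp)
            assert res.mask.n_selected == 3

    def test_nonpositive_m_rejected(self, three_var_q):
        with pytest.raises(InvalidParameterError):
            add_cardinality_penalty(three_var_q, k=1, M=0.0)


class TestContributionRanking:
    def test_single_feature_delta_is_its_diagonal(self, three_var_q):
        order, deltas = rank_by_contribution(
            three_var_q, FeatureMask([0, 0, 1])
        )
        assert order.tolist() == [3]
        assert deltas[0] == pytest.approx(-0.2)

    def test_diagonal_only_orders_most_negative_first(self):
        Q = QuboMatrix(np.diag([-3.0, -1.0, -2.0]))
        order, _ = rank_by_contribution(Q, FeatureMask([1, 1, 1]))
        assert order.tolist() == [1, 3, 2]

    def test_deltas_conserve_total_energy(self):
        rng = np.random.default_rng(3)
        from .conftest import random_qubo

        for _ in range(10):
            Q = random_qubo(rng, 6)
            bits = rng.integers(0, 2, 6)
            if bits.sum() == 0:
                bits[0] = 1
            mask = FeatureMask(bits)
            _, deltas = rank_by_contribution(Q, mask)
            assert deltas.sum() == pytest.approx(energy(Q, mask), abs=1e-10)

    def test_extension_past_the_mask_covers_all_features(self, three_var_q):
        order, deltas = rank_by_contribution(
            three_var_q, FeatureMask([0, 1, 0]), extend_to=3
        )
        assert sorted(order.tolist()) == [1, 2, 3]
        assert order[0] == 2  # mask members always come first
        assert deltas.sum() == pytest.approx(
            energy(three_var_q, FeatureMask([1, 1, 1])), abs=1e-10
        )

    def test_empty_mask_rejected(self, three_var_q):
        with pytest.raises(InvalidParameterError):
            rank_by_contribution(three_var_q, FeatureMask([0, 0, 0]))


class TestEnergyPath:
    def test_length_one_path_is_the_diagonal(self, three_var_q):
        assert energy_path(three_var_q, [2]).tolist() == [-1.0]

    def test_full_ordering_ends_at_mask_energy(self, three_var_q):
        path = energy_path(three_var_q, [3, 1, 2])
        assert path[-1] == pytest.approx(
            energy(three_var_q, FeatureMask([1, 1, 1])), abs=1e-12
        )

    def test_greedy_prefixes_dominate_reversed_on_diagonal_qubo(self):
        # sorted-prefix-sums argument, verified on random diagonals
        rng = np.random.default_rng(4)
        for _ in range(20):
            diag = rng.normal(size=6)
            Q = QuboMatrix(np.diag(diag))
            mask = FeatureMask(np.ones(6, dtype=int))
            order, _ = rank_by_contribution(Q, mask)
            forward = energy_path(Q, order)
            backward = energy_path(Q, order[::-1])
            assert np.all(forward <= backward + 1e-12)

    def test_duplicate_index_rejected(self, three_var_q):
        with pytest.raises(InvalidParameterError):
            energy_path(three_var_q, [1, 1])


class TestCooFormat:
    def test_round_trip(self, three_var_q):
        text = to_coo_text(three_var_q)
        Q2 = from_coo_text(text)
        assert np.allclose(Q2.q, three_var_q.q)

    def test_lower_triangle_entry_rejected(self):
        with pytest.raises(DataError):
            from_coo_text("2 1 0.5\n")
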