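import numpy as np
import pytest

from qubofs import (
    FeatureMask,
    generate_design,
    inject_decoys,
    make_benchmark,
    nonlinear_target,
    recovery_accuracy,
    standardize,
)
from qubofs.errors import DataError, InvalidParameterError
from qubofs.synthetic_data import DECOY_INDICES, SOURCE_INDICES, TARGET_FUNCTIONS


class TestGenerateDesign:
    def test_output_shape(self):
        X = generate_design(20, 50, seed=0)
        assert X.shape == (50, 20)

    def test_generator_correlation_diagonal_is_one(self):
        # rebuild the generator correlation matrix from the same seed path
        rng = np.random.default_rng(0)
        B = rng.standard_normal((20, 20))
        C = B.T @ B
        R = C / np.outer(np.sqrt(np.diag(C)), np.sqrt(np.diag(C)))
        assert np.allclose(np.diag(R), 1.0)

    def test_sample_correlation_approaches_generator(self, bench_full):
        # law of large numbers at p = 10,000
        n = 50
        rng = np.random.default_rng(123)
        B = rng.standard_normal((n, n))
        C = B.T @ B
        R = C / np.outer(np.sqrt(np.diag(C)), np.sqrt(np.diag(C)))
        X = generate_design(n, 10_000, seed=123)
        sample = np.corrcoef(X, rowvar=False)
        assert np.max(np.abs(sample - R)) < 0.05

    def test_preconditions(self):
        with pytest.raises(InvalidParameterError):
            generate_design(10, 100)
        with pytest.raises(InvalidParameterError):
            generate_design(30, 20)


class TestInjectDecoys:
    def test_noiseless_copy_at_rho_zero(self):
        X = np.random.default_rng(0).normal(size=(100, 20))
        out = inject_decoys(X, [1, 2], [11, 12], rho=0.0, seed=0)
        assert np.array_equal(out[:, 10], X[:, 0])
        assert np.array_equal(out[:, 11], X[:, 1])

    def test_untouched_columns_are_bitwise_equal(self):
        X = np.random.default_rng(1).normal(size=(100, 20))
        out = inject_decoys(X, [1], [11], rho=0.5, seed=0)
        untouched = [i for i in range(20) if i != 10]
        assert np.array_equal(out[:, untouched], X[:, untouched])

    def test_decoy_correlation_near_analytic_value(self):
        # corr = 1 / sqrt(1 + rho^2) ~ 0.995 at rho = 0.1
        X = np.random.default_rng(2).normal(size=(10_000, 21))
        out = inject_decoys(X, [1], [21], rho=0.1, seed=3)
        r = np.corrcoef(out[:, 0], out[:, 20])[0, 1]
        assert r > 0.99

    def test_index_collision_rejected(self):
        X = np.zeros((30, 25))
        with pytest.raises(InvalidParameterError):
            inject_decoys(X, [1, 2], [2, 3], rho=0.1)


class TestNonlinearTarget:
    def test_deterministic_without_noise(self):
        X = np.random.default_rng(3).normal(size=(200, 20))
        s = [5, 11, 7, 1, 14]
        y1 = nonlinear_target(X, s, noise_scale=0.0)
        y2 = nonlinear_target(X, s, noise_scale=0.0)
        assert np.array_equal(y1, y2)

    @pytest.mark.parametrize("name", sorted(TARGET_FUNCTIONS))
    def test_depends_only_on_source_columns(self, name):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 20))
        s = [5, 11, 7, 1, 14]
        y = nonlinear_target(X, s, noise_scale=0.0, target_function=name)
        X2 = X.copy()
        X2[:, 16] = rng.permutation(X2[:, 16])  # decoy column, not a source
        assert np.array_equal(
            y, nonlinear_target(X2, s, noise_scale=0.0, target_function=name)
        )

    def test_wrong_source_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            nonlinear_target(np.zeros((50, 20)), [1, 2, 3])

    def test_sources_carry_signal_above_permutation_null(self, bench_full):
        from qubofs import mutual_information, quantile_bin

        ty, _ = quantile_bin(bench_full.y, 10)
        rng = np.random.default_rng(0)
        for s in bench_full.source_indices:
            a, _ = quantile_bin(bench_full.X[:, s - 1], 10)
            real = mutual_information(a, ty)
            null = [
                mutual_information(a, rng.permutation(ty)) for _ in range(100)
            ]
            assert real > np.quantile(null, 0.95)


class TestStandardize:
    def test_affine_map_of_target(self):
        _, ys = standardize(np.random.default_rng(0).normal(size=(3, 2)), [2, 4, 6])
        assert ys.tolist() == [0.0, 0.5, 1.0]

    def test_columns_centered_and_scaled(self):
        X = np.random.default_rng(1).normal(loc=5, scale=3, size=(500, 4))
        Xs, ys = standardize(X, X[:, 0])
        assert np.allclose(Xs.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Xs.std(axis=0), 1, atol=1e-10)
        assert ys.min() == 0.0 and ys.max() == 1.0

    def test_idempotent_on_own_output(self):
        X = np.random.default_rng(2).normal(size=(100, 3))
        y = X[:, 0]
        X1, y1 = standardize(X, y)
        X2, y2 = standardize(X1, y1)
        assert np.allclose(X1, X2, atol=1e-10)
        assert np.allclose(y1, y2, atol=1e-12)

    def test_constant_column_left_as_zeros_with_warning(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.warns(UserWarning):
            Xs, _ = standardize(X, np.arange(50.0))
        assert np.all(Xs[:, 0] == 0)

    def test_constant_target_is_an_error(self):
        with pytest.raises(DataError):
            standardize(np.random.default_rng(3).normal(size=(10, 2)), np.ones(10))


class TestMakeBenchmark:
    def test_published_constants(self, bench_full):
        assert bench_full.source_indices == [5, 11, 7, 1, 14]
        assert bench_full.decoy_indices == [16, 17, 18, 19, 20]
        assert bench_full.rho == 0.1
        assert bench_full.n_features == 50
        assert bench_full.n_observations == 10_000

    def test_sources_and_decoys_disjoint(self):
        assert not set(SOURCE_INDICES) & set(DECOY_INDICES)

    def test_reproducible_given_seed(self):
        a = make_benchmark(5, p=200)
        b = make_benchmark(5, p=200)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.y, b.y)


class TestRecoveryAccuracy:
    def test_published_lasso_worked_example(self):
        assert recovery_accuracy([14, 1, 2, 3, 4], [5, 11, 7, 1, 14]) == 40.0

    def test_perfect_and_disjoint(self):
        truth = [5, 11, 7, 1, 14]
        assert recovery_accuracy(truth, truth) == 100.0
        assert recovery_accuracy([2, 3, 4, 6, 8], truth) == 0.0

    def test_accepts_a_feature_mask(self):
        mask = FeatureMask.from_indices([1, 5], 20)
        assert recovery_accuracy(mask, [1, 5, 7, 11, 14]) == 40.0

    def test_empty_truth_rejected(self):
        with pytest.raises(InvalidParameterError):
            recovery_accuracy([1], [])


class TestDecoyDiscrimination:
    def test_no_solution_contains_a_source_with_its_own_decoy(self, bench_full):
        from qubofs import select_features

        result = select_features(bench_full.X, bench_full.y, k=5, seed=0)
        top = set(int(i) for i in result.selected_indices)
        for s, t in zip(bench_full.source_indices, bench_full.decoy_indices):
            assert not ({s, t} <= top)

    def test_decoys_mirror_source_importance_but_are_redundant(self, bench_full):
        from qubofs import compute_importance, compute_redundancy

        I = compute_importance(bench_full.X, bench_full.y).values
        R = compute_redundancy(bench_full.X).values
        for s, t in zip(bench_full.source_indices, bench_full.decoy_indices):
            assert abs(I[s - 1] - I[t - 1]) < 0.02  # near-identical importance
            off = R[s - 1]
            background = np.median(off[off > 0])
            assert R[s - 1, t - 1] > 20 * background  # mutual redundancy dominates
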