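import numpy as np
import pytest

from qubofs import QuboMatrix, make_benchmark


@pytest.fixture(scope="session")
def three_var_q() -> QuboMatrix:
    """Hand-checkable 3-variable QUBO: diag (-1, -1, -0.2), Q12 = Q23 = 0.5.

    Enumerating all 8 masks by hand gives the global minimum at
    x = (1, 1, 0) with energy -1.5.
    """
    q = np.array(
        [
            [-1.0, 0.5, 0.0],
            [0.0, -1.0, 0.5],
            [0.0, 0.0, -0.2],
        ]
    )
    return QuboMatrix(q)


@pytest.fixture(scope="session")
def bench_small():
    """A reduced benchmark instance (2,000 observations) for fast tests."""
    return make_benchmark(seed=0, p=2000)


@pytest.fixture(scope="session")
def bench_full():
    """One full-size benchmark instance (10,000 observations)."""
    return make_benchmark(seed=0)


def random_qubo(rng: np.random.Generator, n: int) -> QuboMatrix:
    """Random dense QUBO with negative-leaning diagonal (selection-like)."""
    q = np.triu(rng.normal(scale=0.5, size=(n, n)), k=1)
    q[np.diag_indices(n)] = rng.normal(loc=-0.5, scale=0.5, size=n)
    return QuboMatrix(q)
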