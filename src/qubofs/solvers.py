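"""Classical minimizers for the QUBO selection objective.

Three backends share one interface: an exhaustive oracle (small problems
only), single-flip Metropolis simulated annealing with a geometric
inverse-temperature schedule, and an iterated tabu search (steepest-descent
single-flip moves, recency tabu list with aspiration, random restarts).
The same interface is what a quantum-hardware adapter would implement; no
hardware code ships here, and on every problem tested the classical
heuristics agree with each other and with the oracle, which is the
behaviour the method relies on.

All solvers are deterministic given their seed.  Whenever the best state
found has positive energy, the empty mask (energy 0) is returned instead:
selecting nothing is always admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import CapacityError, DataError, InvalidParameterError
from .qubo_core import FeatureMask, QuboMatrix, energy

EXHAUSTIVE_MAX_BITS = 25
_CHUNK_BITS = 18


@dataclass
class SolverResult:
    """A solver's best mask with its (recomputed) energy and metadata."""

    mask: FeatureMask
    energy: float
    backend: str
    seed: int | None = None
    iterations: int = 0
    trajectory: list[float] | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def create(cls, Q: QuboMatrix, bits: np.ndarray, backend: str, **kw) -> "SolverResult":
        mask = FeatureMask(bits)
        return cls(mask=mask, energy=energy(Q, mask), backend=backend, **kw)


def solve_exhaustive(Q: QuboMatrix) -> SolverResult:
    """Global minimum by enumeration of all 2^n masks (n <= 25).

    Among energy ties the lexicographically smallest bit vector wins;
    enumeration order makes that the first minimum encountered.
    """
    n = Q.n_features
    if n > EXHAUSTIVE_MAX_BITS:
        raise CapacityError(
            f"exhaustive enumeration limited to {EXHAUSTIVE_MAX_BITS} bits, got {n}"
        )
    diag = Q.diagonal()
    U = np.triu(Q.q, k=1)
    best_e = np.inf
    best_bits = np.zeros(n, dtype=np.int8)
    # feature 0 is the most significant bit so integer order == lex order
    shifts = np.arange(n - 1, -1, -1, dtype=np.uint64)
    for start in range(0, 2**n, 2**_CHUNK_BITS):
        stop = min(start + 2**_CHUNK_BITS, 2**n)
        codes = np.arange(start, stop, dtype=np.uint64)
        bits = ((codes[:, None] >> shifts) & 1).astype(np.float64)
        energies = bits @ diag + np.einsum("ki,ij,kj->k", bits, U, bits, optimize=True)
        i = int(np.argmin(energies))
        if energies[i] < best_e:
            best_e = float(energies[i])
            best_bits = bits[i].astype(np.int8)
    return SolverResult.create(
        Q, best_bits, backend="exhaustive", iterations=2**n
    )


def _auto_beta_range(diag: np.ndarray, S: np.ndarray) -> tuple[float, float]:
    """Inverse-temperature range scaled to the problem's single-flip deltas.

    The hot end accepts the largest possible uphill flip with probability
    ~1/2; the cold end rejects the smallest meaningful flip with
    probability ~99%.  This mirrors the standard auto-schedule of QUBO
    annealers, and matters here because mutual-information QUBOs have
    couplings of order 1e-2 nats rather than order 1.
    """
    bound = np.abs(diag) + np.abs(S).sum(axis=1)
    hot = float(bound.max())
    nonzero = bound[bound > 0]
    cold = float(np.abs(diag)[np.abs(diag) > 0].min()) if np.any(diag) else (
        float(nonzero.min()) if len(nonzero) else 1.0
    )
    if hot <= 0:
        return (0.1, 10.0)
    return (np.log(2.0) / hot, np.log(100.0) / min(cold, hot))


def solve_simulated_annealing(
    Q: QuboMatrix,
    n_sweeps: int = 1000,
    n_restarts: int = 10,
    beta_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> SolverResult:
    """Single-flip Metropolis annealing, vectorized across restarts.

    One sweep proposes ``n`` flips at uniformly random positions in every
    restart chain; the inverse temperature follows a geometric schedule
    across sweeps.  With ``beta_range=None`` the schedule endpoints are
    derived from the problem's own energy scale (see
    :func:`_auto_beta_range`).
    """
    if n_sweeps <= 0 or n_restarts <= 0:
        raise InvalidParameterError("sweep and restart counts must be positive")
    n = Q.n_features
    diag = Q.diagonal()
    S = Q.symmetric_offdiag()
    if beta_range is None:
        beta_range = _auto_beta_range(diag, S)
    b0, b1 = beta_range
    if not (0 < b0 < b1):
        raise InvalidParameterError(f"beta schedule must be increasing and positive, got {beta_range}")
    rng = np.random.default_rng(seed)

    X = (rng.random((n_restarts, n)) < 0.5).astype(np.float64)
    coupling = X @ S
    E = X @ diag + 0.5 * np.einsum("ri,ri->r", X, coupling)
    best_E = E.copy()
    best_X = X.copy()
    rows = np.arange(n_restarts)
    betas = np.geomspace(b0, b1, n_sweeps)
    for beta in betas:
        cols = rng.integers(0, n, size=(n, n_restarts))
        unif = rng.random((n, n_restarts))
        for step in range(n):
            i = cols[step]
            xi = X[rows, i]
            delta = (1.0 - 2.0 * xi) * (diag[i] + coupling[rows, i])
            accept = (delta <= 0) | (unif[step] < np.exp(-beta * np.clip(delta, 0, 700)))
            if accept.any():
                r = rows[accept]
                ia = i[accept]
                sign = 1.0 - 2.0 * X[r, ia]
                X[r, ia] += sign
                E[accept] += delta[accept]
                coupling[accept] += sign[:, None] * S[ia]
                improved = accept & (E < best_E - 1e-15)
                if improved.any():
                    best_E[improved] = E[improved]
                    best_X[improved] = X[improved]
    return _finish(
        Q,
        best_X,
        best_E,
        backend="sa",
        seed=seed,
        iterations=n_sweeps * n * n_restarts,
        params={"n_sweeps": n_sweeps, "n_restarts": n_restarts, "beta_range": beta_range},
    )


def solve_tabu(
    Q: QuboMatrix,
    n_iters: int = 500,
    tabu_tenure: int | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> SolverResult:
    """Iterated tabu search: steepest single-flip moves with aspiration.

    Each restart starts from a fresh random mask and performs ``n_iters``
    moves; a flipped bit becomes tabu for ``tabu_tenure`` moves unless
    flipping it would improve on the incumbent (aspiration).  With
    ``n_iters=0`` the result is simply the best of the random initial
    masks (or the empty mask if they are all worse than it).
    """
    if n_iters < 0 or n_restarts <= 0:
        raise InvalidParameterError("iteration and restart counts must be valid")
    n = Q.n_features
    if tabu_tenure is None:
        tabu_tenure = max(7, n // 10)
    if tabu_tenure <= 0:
        raise InvalidParameterError("tabu tenure must be positive")
    diag = Q.diagonal()
    S = Q.symmetric_offdiag()
    rng = np.random.default_rng(seed)

    best_X = np.zeros((n_restarts, n))
    best_E = np.full(n_restarts, np.inf)
    for r in range(n_restarts):
        x = (rng.random(n) < 0.5).astype(np.float64)
        coupling = S @ x
        E = float(x @ diag + 0.5 * x @ coupling)
        inc_E, inc_x = E, x.copy()
        expiry = np.zeros(n, dtype=np.int64)
        for it in range(1, n_iters + 1):
            delta = (1.0 - 2.0 * x) * (diag + coupling)
            blocked = (expiry >= it) & (E + delta >= inc_E - 1e-15)  # aspiration
            cand = np.where(blocked, np.inf, delta)
            i = int(np.argmin(cand))
            if not np.isfinite(cand[i]):
                break  # every move tabu and none aspirates
            sign = 1.0 - 2.0 * x[i]
            x[i] += sign
            coupling += sign * S[:, i]
            E += float(delta[i])
            expiry[i] = it + tabu_tenure
            if E < inc_E - 1e-15:
                inc_E, inc_x = E, x.copy()
        best_E[r] = inc_E
        best_X[r] = inc_x
    return _finish(
        Q,
        best_X,
        best_E,
        backend="tabu",
        seed=seed,
        iterations=n_iters * n_restarts,
        params={"n_iters": n_iters, "tabu_tenure": tabu_tenure, "n_restarts": n_restarts},
    )


def _finish(Q, best_X, best_E, backend, seed, iterations, params) -> SolverResult:
    """Pick the best restart (lexicographic tie-break) with empty-mask fallback."""
    order = np.argsort(best_E, kind="stable")
    top = order[np.isclose(best_E[order], best_E[order[0]], rtol=0, atol=0)]
    winner = min((tuple(best_X[r].astype(int)) for r in top))
    bits = np.asarray(winner, dtype=np.int8)
    if energy(Q, FeatureMask(bits)) > 0:
        bits = np.zeros(Q.n_features, dtype=np.int8)
    return SolverResult.create(
        Q,
        bits,
        backend=backend,
        seed=seed,
        iterations=iterations,
        trajectory=[float(e) for e in best_E],
        params=params,
    )


BACKENDS: dict[str, Callable[..., SolverResult]] = {
    "exhaustive": lambda Q, seed=0, **p: solve_exhaustive(Q),
    "sa": lambda Q, seed=0, **p: solve_simulated_annealing(Q, seed=seed, **p),
    "tabu": lambda Q, seed=0, **p: solve_tabu(Q, seed=seed, **p),
}


def get_backend(name: str) -> Callable[..., SolverResult]:
    try:
        return BACKENDS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown backend {name!r}; available: {sorted(BACKENDS)}"
        ) from None


def solve(Q: QuboMatrix, backend: str = "tabu", seed: int = 0, **params) -> SolverResult:
    """Minimize ``Q`` with the named backend."""
    return get_backend(backend)(Q, seed=seed, **params)
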