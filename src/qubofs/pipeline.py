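"""End-to-end selection: MI estimation -> QUBO -> solve -> rank.

Two cardinality mechanisms are supported.  The default (``"rank"``)
solves the unconstrained QUBO and ranks features by greedy energy
contribution, extending the ranking past the solver mask when it holds
fewer than ``k`` bits; this mirrors how the method ranks features far
beyond the unconstrained minimizer.  The alternative (``"penalty"``)
adds the k-hot penalty ``M (sum x_i - k)^2`` before solving.  The
mechanism used is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .mutual_info import (
    DEFAULT_BINS,
    ImportanceVector,
    RedundancyMatrix,
    _as_matrix,
    compute_importance,
    compute_redundancy,
)
from .qubo_core import (
    FeatureMask,
    QuboMatrix,
    build_qubo,
    energy,
    rank_by_contribution,
    add_cardinality_penalty,
)
from .solvers import SolverResult, solve

DEFAULT_ALPHA = 0.8


@dataclass
class SelectionResult:
    """Ranked features with the QUBO and solver evidence behind them."""

    ranking: np.ndarray  # 1-based feature indices, contribution order
    deltas: np.ndarray  # per-feature energy contribution
    mask: FeatureMask  # the k-feature (or unconstrained) selection
    solver_result: SolverResult
    qubo: QuboMatrix
    importance: ImportanceVector
    redundancy: RedundancyMatrix
    params: dict = field(default_factory=dict)

    @property
    def selected_indices(self) -> np.ndarray:
        return self.mask.selected_indices

    @property
    def selected_names(self) -> list[str] | None:
        names = self.importance.feature_names
        if names is None:
            return None
        return [names[i - 1] for i in self.selected_indices]


def select_features(
    X,
    T,
    k: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_bins: int = DEFAULT_BINS,
    backend: str = "tabu",
    seed: int = 0,
    cardinality: str = "rank",
    solver_params: dict | None = None,
) -> SelectionResult:
    """Select (up to) ``k`` features predictive of target ``T``.

    With ``k=None`` the unconstrained solver mask is returned as-is,
    ranked by contribution.
    """
    Xa, _ = _as_matrix(X)
    n = Xa.shape[1]
    if k is not None and not 1 <= k <= n:
        raise InvalidParameterError(f"k must lie in 1..{n}, got {k}")
    if cardinality not in ("rank", "penalty"):
        raise InvalidParameterError(f"unknown cardinality mechanism {cardinality!r}")
    solver_params = solver_params or {}

    I = compute_importance(X, T, n_bins)
    R = compute_redundancy(X, n_bins)
    Q = build_qubo(I, R, alpha)

    if cardinality == "penalty" and k is not None:
        Qp = add_cardinality_penalty(Q, k)
        res = solve(Qp, backend=backend, seed=seed, **solver_params)
        base = res.mask if res.mask.n_selected else FeatureMask(np.ones(n, dtype=np.int8))
        order, deltas = rank_by_contribution(Q, base, extend_to=n)
        top = order[:k]
    else:
        res = solve(Q, backend=backend, seed=seed, **solver_params)
        base = res.mask
        if base.n_selected == 0:
            # nothing clears the redundancy bar; rank from scratch
            base = FeatureMask(np.ones(n, dtype=np.int8))
        # the full contribution ordering: solver-mask members first, then
        # the remaining features greedily (rankings beyond k stay usable)
        order, deltas = rank_by_contribution(Q, base, extend_to=n)
        top = order[:k] if k is not None else order[: base.n_selected]
    mask = FeatureMask.from_indices(top, n)
    return SelectionResult(
        ranking=order,
        deltas=deltas,
        mask=mask,
        solver_result=res,
        qubo=Q,
        importance=I,
        redundancy=R,
        params={
            "k": k,
            "alpha": alpha,
            "n_bins": n_bins,
            "backend": backend,
            "seed": seed,
            "cardinality": cardinality,
        },
    )


def alpha_sweep(X, T, alphas, k: int, **kwargs) -> dict[float, SelectionResult]:
    """Run selection at each alpha; useful for balance diagnostics."""
    return {float(a): select_features(X, T, k=k, alpha=float(a), **kwargs) for a in alphas}
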