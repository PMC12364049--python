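"""Stability diagnostics: k-fold robustness, energy paths, landscapes.

The k-fold analysis rebuilds a *local* cost function Q' from each fold's
observation subset, solves it, and scores the fold's selection both
against Q' and against the *global* cost function Q built from all
observations.  Fold accuracy is the overlap of the fold's top-k selection
with the full-data top-k selection, as a percentage of k — the most
direct reading of per-fold selection accuracy; it compares masks, not
energies.  Folds partition observations (cells); by default each fold's
local subset is the training complement (the usual (k-1)/k share) of a
seeded shuffled partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, InvalidParameterError
from .mutual_info import DEFAULT_BINS, _as_matrix
from .pipeline import DEFAULT_ALPHA, select_features
from .qubo_core import FeatureMask, QuboMatrix, energy, energy_path

_SEED_MOD = 2**31 - 1


@dataclass
class FoldRecord:
    fold: int
    selected: np.ndarray  # 1-based indices
    local_energy: float  # energy of the fold's mask under Q'
    global_energy: float  # energy of the fold's mask under Q
    accuracy: float  # % overlap with the full-data selection


@dataclass
class CVReport:
    folds: list[FoldRecord]
    full_data_selected: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def min_accuracy(self) -> float:
        return float(np.min([f.accuracy for f in self.folds]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": [f.fold for f in self.folds],
                "selected": [",".join(map(str, f.selected)) for f in self.folds],
                "local_energy": [f.local_energy for f in self.folds],
                "global_energy": [f.global_energy for f in self.folds],
                "accuracy": [f.accuracy for f in self.folds],
            }
        )


def kfold_stability(
    X,
    T,
    k_features: int,
    n_folds: int = 10,
    alpha: float = DEFAULT_ALPHA,
    n_bins: int = DEFAULT_BINS,
    backend: str = "tabu",
    seed: int = 0,
    subsets: Sequence[np.ndarray] | None = None,
) -> CVReport:
    """Cross-validated selection stability against the full-data solution.

    ``subsets`` overrides the default fold construction with explicit
    observation-index arrays (one local cost function per subset); passing
    copies of the full index range degenerates to accuracy 100 everywhere.
    A subset too small for ``n_bins`` quantile bins is binned coarser,
    with a warning.
    """
    Xa, _ = _as_matrix(X)
    T = np.asarray(T, dtype=float).ravel()
    p = Xa.shape[0]
    if subsets is None:
        if n_folds < 2:
            raise InvalidParameterError("need at least 2 folds")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(p)
        held = [perm[i::n_folds] for i in range(n_folds)]  # round-robin after shuffle
        subsets = [np.setdiff1d(perm, h) for h in held]

    full = select_features(
        Xa, T, k=k_features, alpha=alpha, n_bins=n_bins, backend=backend, seed=seed
    )
    Q = full.qubo
    full_set = set(int(i) for i in full.selected_indices)

    records = []
    for f, idx in enumerate(subsets):
        idx = np.asarray(idx, dtype=np.int64)
        fold_bins = n_bins
        if len(idx) < n_bins:
            fold_bins = max(2, len(idx))
            warnings.warn(
                f"fold {f}: only {len(idx)} observations; reducing bins to {fold_bins}"
            )
        local = select_features(
            Xa[idx],
            T[idx],
            k=k_features,
            alpha=alpha,
            n_bins=fold_bins,
            backend=backend,
            seed=(seed + 7919 * (f + 1)) % _SEED_MOD,
        )
        mask = FeatureMask.from_indices(local.selected_indices, Q.n_features)
        acc = 100.0 * len(set(int(i) for i in local.selected_indices) & full_set) / k_features
        records.append(
            FoldRecord(
                fold=f,
                selected=local.selected_indices,
                local_energy=energy(local.qubo, mask),
                global_energy=energy(Q, mask),
                accuracy=acc,
            )
        )
    return CVReport(
        folds=records,
        full_data_selected=full.selected_indices,
        params={
            "k_features": k_features,
            "n_folds": len(subsets),
            "alpha": alpha,
            "n_bins": n_bins,
            "backend": backend,
            "seed": seed,
        },
    )


def compare_energy_paths(
    Q: QuboMatrix, method_orderings: dict[str, Sequence[int]]
) -> pd.DataFrame:
    """Cumulative energy of each method's feature ordering under one Q.

    Rows are prefix lengths (1-based); one column per method.  Orderings
    of different lengths are aligned on the shortest common prefix range,
    padded with NaN beyond a method's length.
    """
    paths = {name: energy_path(Q, order) for name, order in method_orderings.items()}
    longest = max(len(p) for p in paths.values())
    table = pd.DataFrame(
        {
            name: np.concatenate([p, np.full(longest - len(p), np.nan)])
            for name, p in paths.items()
        },
        index=pd.RangeIndex(1, longest + 1, name="prefix_length"),
    )
    return table


def landscape_enumeration(
    Q: QuboMatrix,
    candidate_features: Sequence[int],
    subset_size: int,
    max_combinations: int = 10**6,
) -> pd.DataFrame:
    """Energies of every ``subset_size``-combination of the candidates.

    Candidates are 1-based feature indices; the result has one row per
    combination with its member indices and energy.
    """
    cands = np.asarray(list(candidate_features), dtype=np.int64)
    if len(np.unique(cands)) != len(cands):
        raise InvalidParameterError("candidate features contain duplicates")
    if cands.min() < 1 or cands.max() > Q.n_features:
        raise InvalidParameterError("candidate index out of range")
    from math import comb

    n_comb = comb(len(cands), subset_size)
    if n_comb > max_combinations:
        raise CapacityError(
            f"{n_comb} combinations exceed the {max_combinations} cap"
        )
    combos = np.array(list(combinations(cands, subset_size)), dtype=np.int64)
    diag = Q.diagonal()
    S = Q.symmetric_offdiag()
    zero = combos - 1
    energies = diag[zero].sum(axis=1)
    for a in range(subset_size):
        for b in range(a + 1, subset_size):
            energies = energies + 0.5 * (
                S[zero[:, a], zero[:, b]] + S[zero[:, b], zero[:, a]]
            )
    out = pd.DataFrame(
        {
            "members": [tuple(int(i) for i in row) for row in combos],
            "energy": energies,
        }
    )
    return out
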