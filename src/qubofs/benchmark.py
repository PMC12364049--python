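"""Benchmark harness: QUBO selection vs. reference baseline selectors.

Each baseline is a thin adapter around a reference implementation
(scikit-learn where one exists) returning its top-k features as 1-based
indices; the harness scores every method's selection against the planted
source set with :func:`~qubofs.synthetic_data.recovery_accuracy`.

Baseline notes
--------------
* ``lasso`` / ``elastic_net`` rank features by the order in which they
  enter the regularization path (largest penalty first); features that
  never activate are appended in index order — which is also what a
  ranking by shrunken coefficients degenerates to when fewer than k
  coefficients are ever nonzero.
* ``rfr`` ranks by impurity-based feature importances of a default
  :class:`~sklearn.ensemble.RandomForestRegressor`.
* ``mrmr`` is the original algorithm's continuous-data scheme: F-statistic
  relevance against mean absolute Pearson correlation redundancy,
  difference form (FCD).
* ``sfs`` is greedy forward selection of a linear model by
  cross-validated R^2.
* ``relieff`` has no reference implementation in this environment and is
  registered as unavailable; the harness skips it with a warning.

Wall-clock time per method is recorded informationally alongside the
accuracies.
"""

from __future__ import annotations

import logging
import time
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import InvalidParameterError, UnavailableMethodError
from .pipeline import select_features
from .synthetic_data import SyntheticDataset, make_benchmark, recovery_accuracy

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


def _select_qubo(X, y, k, seed):
    return list(select_features(X, y, k=k, seed=seed).selected_indices)


def _path_order(alphas, coefs, k):
    """Rank features by first activation along a decreasing-penalty path."""
    n = coefs.shape[0]
    active = np.abs(coefs) > 1e-12
    first = np.where(active.any(axis=1), active.argmax(axis=1), coefs.shape[1] + n)
    order = np.argsort(first, kind="stable")  # ties -> index order
    return [int(i) + 1 for i in order[:k]]


def _select_lasso(X, y, k, seed):
    from sklearn.linear_model import lasso_path

    alphas, coefs, _ = lasso_path(X, y)
    return _path_order(alphas, coefs, k)


def _select_elastic_net(X, y, k, seed):
    from sklearn.linear_model import enet_path

    alphas, coefs, _ = enet_path(X, y, l1_ratio=0.5)
    return _path_order(alphas, coefs, k)


def _select_rfr(X, y, k, seed):
    from sklearn.ensemble import RandomForestRegressor

    model = RandomForestRegressor(random_state=seed)
    model.fit(X, y)
    order = np.argsort(model.feature_importances_, kind="stable")[::-1]
    return [int(i) + 1 for i in order[:k]]


def _select_sfs(X, y, k, seed):
    from sklearn.feature_selection import SequentialFeatureSelector
    from sklearn.linear_model import LinearRegression

    sel = SequentialFeatureSelector(
        LinearRegression(), n_features_to_select=k, direction="forward"
    )
    sel.fit(X, y)
    return [int(i) + 1 for i in np.flatnonzero(sel.get_support())]


def _select_mrmr(X, y, k, seed):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[1]
    p = len(y)
    r = np.array([_stats.pearsonr(X[:, i], y)[0] for i in range(n)])
    F = (r**2 * (p - 2)) / np.maximum(1.0 - r**2, 1e-12)
    C = np.abs(np.corrcoef(X, rowvar=False))
    chosen = [int(np.argmax(F))]
    while len(chosen) < k:
        score = np.full(n, -np.inf)
        for c in range(n):
            if c in chosen:
                continue
            score[c] = F[c] - float(np.mean(C[c, chosen]))
        chosen.append(int(np.argmax(score)))
    return [c + 1 for c in chosen]


def _select_relieff(X, y, k, seed):
    raise UnavailableMethodError(
        "RReliefF has no reference implementation in this environment"
    )


METHODS: dict[str, Callable] = {
    "qubo": _select_qubo,
    "lasso": _select_lasso,
    "elastic_net": _select_elastic_net,
    "rfr": _select_rfr,
    "relieff": _select_relieff,
    "sfs": _select_sfs,
    "mrmr": _select_mrmr,
}


def run_benchmark(
    methods: Sequence[str],
    k_features: int = 5,
    n_replicates: int = 20,
    seed: int = 0,
    dataset: SyntheticDataset | None = None,
    **generator_kwargs,
) -> pd.DataFrame:
    """Score each method's top-k recovery of the planted sources.

    With ``dataset=None`` (the default) every replicate regenerates the
    benchmark from a replicate-specific seed, exposing the stochastic
    spread of both data and method; passing a fixed ``dataset`` varies
    only the method seed.  The returned frame holds replicate-level raw
    values (method, replicate, seed, accuracy, selected indices, seconds),
    never just means; ``summarize_benchmark`` aggregates it.
    """
    for m in methods:
        if m not in METHODS:
            raise InvalidParameterError(
                f"unknown method {m!r}; available: {sorted(METHODS)}"
            )
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed + 104729 * rep) % _SEED_MOD
        data = dataset if dataset is not None else make_benchmark(rep_seed, **generator_kwargs)
        truth = data.source_indices
        for m in methods:
            t0 = time.perf_counter()
            try:
                selected = METHODS[m](data.X, data.y, k_features, rep_seed)
            except UnavailableMethodError as exc:
                logger.warning("skipping %s: %s", m, exc)
                continue
            elapsed = time.perf_counter() - t0
            rows.append(
                {
                    "method": m,
                    "replicate": rep,
                    "seed": rep_seed,
                    "accuracy": recovery_accuracy(selected, truth),
                    "selected": ",".join(str(int(i)) for i in selected),
                    "seconds": elapsed,
                }
            )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/modal accuracy and mean runtime per method."""
    def _mode(s):
        return float(s.mode().iloc[0])

    out = table.groupby("method")["accuracy"].agg(["mean", "min", "max", _mode])
    out = out.rename(columns={"_mode": "mode"})
    out["seconds"] = table.groupby("method")["seconds"].mean()
    return out.sort_values("mean", ascending=False)
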