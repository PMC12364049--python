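"""Quantile-binned mutual-information estimation.

Continuous features and the continuous regression target are discretized
into ``B`` quantile bins; importance ``I_i`` is the plug-in mutual
information between binned feature *i* and the binned target, and
redundancy ``R_ij`` is the plug-in mutual information between binned
features *i* and *j*.  All values are reported in nats (natural log);
since importance and redundancy are scaled identically by the log base,
the minimizer of the downstream QUBO objective does not depend on it.

Quantile edges that coincide because of tied data are collapsed, so the
effective number of bins may be smaller than ``B`` for heavily tied
features (common for sparse expression values); labels stay contiguous
``1..B_eff``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InvalidParameterError

DEFAULT_BINS = 10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DiscretizedDataset:
    """Integer bin labels plus the quantile boundaries that produced them.

    Attributes
    ----------
    labels
        ``(p, n)`` integer matrix of bin labels in ``1..bin_count``.
    boundaries
        Per-feature ordered vectors of quantile edges (length ``B_eff + 1``
        after collapsing duplicate edges).
    bin_count
        The requested number of bins ``B`` (>= 2).
    target_labels
        Bin labels of the target variable, present whenever a target was
        discretized alongside the features.
    """

    labels: np.ndarray
    boundaries: list[np.ndarray]
    bin_count: int
    target_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.bin_count:
            raise DataError("bin labels must lie in [1, bin_count]")
        for b in self.boundaries:
            if np.any(np.diff(b) < 0):
                raise DataError("bin boundaries must be non-decreasing")

    @property
    def n_observations(self) -> int:
        return self.labels.shape[0]

    @property
    def n_features(self) -> int:
        return self.labels.shape[1]


@dataclass
class ImportanceVector:
    """Mutual information between each feature and the target, in nats."""

    values: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise DataError("mutual information must be nonnegative")
        self.values = np.maximum(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RedundancyMatrix:
    """Symmetric pairwise mutual information with a structural zero diagonal.

    A feature is never redundant with itself, so the diagonal is fixed at
    zero rather than at the feature's entropy.
    """

    values: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("redundancy matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("redundancy matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise DataError("redundancy diagonal must be exactly zero")
        if np.any(v < -1e-12):
            raise DataError("mutual information must be nonnegative")
        self.values = np.maximum(v, 0.0)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def quantile_bin(values, n_bins: int = DEFAULT_BINS):
    """Discretize ``values`` into ``n_bins`` quantile bins.

    Bin ``L`` is the half-open interval ``(q_{L-1}, q_L]``; the lowest bin
    is closed on the left so the minimum lands in bin 1.  Ties that fall
    exactly on a shared boundary all receive the same label.  Duplicate
    quantile edges are collapsed, so fewer than ``n_bins`` labels may be
    used; labels remain contiguous starting at 1.

    Returns
    -------
    labels : ndarray of int
        1-based bin labels, same length as ``values``.
    boundaries : ndarray
        The (deduplicated) quantile edges, ``B_eff + 1`` values.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise InvalidParameterError(f"n_bins must be >= 2, got {n_bins}")
    if values.ndim != 1:
        raise DataError("quantile_bin expects a 1-D vector")
    if len(values) < n_bins:
        raise InvalidParameterError(
            f"need at least n_bins={n_bins} observations, got {len(values)}"
        )
    if not np.all(np.isfinite(values)):
        raise DataError("values must be finite")
    edges = np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)  # collapse ties -> contiguous labels
    # searchsorted against the interior edges: v <= e_L  =>  bin L
    labels = np.searchsorted(edges[1:-1], values, side="left") + 1
    return labels.astype(np.int64), edges


def discretize(X, T=None, n_bins: int = DEFAULT_BINS) -> DiscretizedDataset:
    """Quantile-bin every column of ``X`` (and optionally the target ``T``)."""
    X = _as_matrix(X)[0]
    labels = np.empty(X.shape, dtype=np.int64)
    boundaries = []
    for j in range(X.shape[1]):
        labels[:, j], edges = quantile_bin(X[:, j], n_bins)
        boundaries.append(edges)
    target_labels = None
    if T is not None:
        T = np.asarray(T, dtype=float).ravel()
        if len(T) != X.shape[0]:
            raise DataError("target length must match the number of observations")
        target_labels, _ = quantile_bin(T, n_bins)
    return DiscretizedDataset(labels, boundaries, n_bins, target_labels)


def empirical_joint_pmf(a, b) -> np.ndarray:
    """Empirical joint probability table of two 1-based label vectors.

    Entry ``(u, v)`` is the fraction of observations with ``a == u+1`` and
    ``b == v+1``; the table is square over the larger label range of the
    two inputs and its entries sum to 1.
    """
    a = np.asarray(a, dtype=np.int64).ravel()
    b = np.asarray(b, dtype=np.int64).ravel()
    if len(a) != len(b):
        raise DataError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise DataError("label vectors must be non-empty")
    if a.min() < 1 or b.min() < 1:
        raise DataError("labels must be 1-based positive integers")
    n_levels = int(max(a.max(), b.max()))
    counts = np.bincount((a - 1) * n_levels + (b - 1), minlength=n_levels * n_levels)
    return counts.reshape(n_levels, n_levels) / len(a)


def mutual_information(a, b) -> float:
    """Plug-in mutual information (nats) of two discretized vectors.

    Computed as ``sum p(u,v) log[p(u,v) / (p(u) p(v))]`` over cells with
    positive joint mass; empty cells contribute zero by the convention
    ``0 log 0 := 0``.
    """
    joint = empirical_joint_pmf(a, b)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(pa, pb)[mask]
    terms = joint[mask] * np.log(joint[mask] / outer)
    # summing in sorted order makes MI(a, b) == MI(b, a) bit-exact: the
    # transposed table yields the same multiset of cell contributions
    mi = float(np.sort(terms).sum())
    return max(mi, 0.0)


def compute_importance(X, T, n_bins: int = DEFAULT_BINS) -> ImportanceVector:
    """Mutual information between each binned feature and the binned target."""
    X, names = _as_matrix(X)
    T = np.asarray(T, dtype=float).ravel()
    if len(T) != X.shape[0]:
        raise DataError("target length must match the number of observations")
    ds = discretize(X, T, n_bins)
    t = ds.target_labels
    values = np.array(
        [mutual_information(ds.labels[:, j], t) for j in range(ds.n_features)]
    )
    return ImportanceVector(values, names)


def compute_redundancy(X, n_bins: int = DEFAULT_BINS) -> RedundancyMatrix:
    """Pairwise mutual information between binned features (zero diagonal)."""
    X, names = _as_matrix(X)
    ds = discretize(X, n_bins=n_bins)
    n = ds.n_features
    labels0 = ds.labels - 1  # 0-based for flat encoding
    values = np.zeros((n, n))
    for i in range(n):
        ai = labels0[:, i]
        for j in range(i + 1, n):
            counts = np.bincount(ai * n_bins + labels0[:, j], minlength=n_bins * n_bins)
            joint = counts.reshape(n_bins, n_bins) / len(ai)
            values[i, j] = values[j, i] = _mi_from_joint(joint)
    return RedundancyMatrix(values, names)


def _as_matrix(X):
    """Coerce an expression matrix (DataFrame or array) to (ndarray, names)."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("expression matrix must be 2-D (observations x features)")
    return X, None
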