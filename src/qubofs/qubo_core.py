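"""QUBO cost-matrix construction and energy accounting.

The selection objective is

    E(x) = -alpha * sum_i I_i x_i  +  (1 - alpha) * sum_{i != j} R_ij x_i x_j

over binary masks ``x``; in matrix form ``E(x) = x^T Q x`` with ``Q``
stored upper-triangular: diagonal ``-alpha * I_i`` and upper off-diagonal
``(1 - alpha) * (R_ij + R_ji)``.  Folding both ordered pairs of the
symmetric redundancy matrix into the single upper entry is what makes the
quadratic form reproduce the double sum; it is also the one place where a
factor-2 discrepancy with other QUBO conventions can arise, so it is
documented here and nowhere re-derived.

Feature indices in public inputs/outputs are 1-based, matching the gene
lists and index sets this package exchanges with its file formats.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, InvalidParameterError
from .mutual_info import ImportanceVector, RedundancyMatrix


@dataclass
class QuboMatrix:
    """Upper-triangular QUBO matrix over ``n_features`` binary variables."""

    q: np.ndarray
    alpha: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise DataError("QUBO matrix must be square")
        if np.any(np.tril(q, k=-1) != 0):
            raise DataError("QUBO matrix must be upper-triangular")
        self.q = q

    @property
    def n_features(self) -> int:
        return self.q.shape[0]

    def diagonal(self) -> np.ndarray:
        return np.diag(self.q).copy()

    def symmetric_offdiag(self) -> np.ndarray:
        """Symmetrized off-diagonal part: S = U + U^T with zero diagonal."""
        off = self.q - np.diag(np.diag(self.q))
        return off + off.T


@dataclass
class FeatureMask:
    """Binary selection vector; ``bits[i] == 1`` selects feature ``i + 1``."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1 or not np.all(np.isin(bits, (0, 1))):
            raise DataError("mask bits must be a 1-D 0/1 vector")
        self.bits = bits.astype(np.int8)

    @classmethod
    def from_indices(cls, indices: Sequence[int], n_features: int) -> "FeatureMask":
        """Build a mask from 1-based feature indices."""
        idx = np.asarray(list(indices), dtype=np.int64)
        if len(idx) and (idx.min() < 1 or idx.max() > n_features):
            raise InvalidParameterError("feature indices must lie in 1..n_features")
        if len(np.unique(idx)) != len(idx):
            raise InvalidParameterError("duplicate feature index in mask")
        bits = np.zeros(n_features, dtype=np.int8)
        bits[idx - 1] = 1
        return cls(bits)

    @property
    def selected_indices(self) -> np.ndarray:
        """1-based indices of the selected features."""
        return np.flatnonzero(self.bits) + 1

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return len(self.bits)


def build_qubo(I, R, alpha: float) -> QuboMatrix:
    """Combine importance and redundancy into the upper-triangular QUBO.

    ``alpha = 1`` leaves only the (negative) importance diagonal, so
    minimization selects every feature with positive importance;
    ``alpha = 0`` leaves only nonnegative redundancy couplings, whose
    global minimum is the empty mask.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError(f"alpha must lie in [0, 1], got {alpha}")
    I_vals = I.values if isinstance(I, ImportanceVector) else np.asarray(I, dtype=float)
    R_vals = R.values if isinstance(R, RedundancyMatrix) else np.asarray(R, dtype=float)
    n = len(I_vals)
    if R_vals.shape != (n, n):
        raise DataError(f"redundancy shape {R_vals.shape} does not match {n} features")
    if np.any(np.diag(R_vals) != 0):
        raise DataError("redundancy diagonal must be zero")
    q = np.triu((1.0 - alpha) * (R_vals + R_vals.T), k=1)
    np.fill_diagonal(q, -alpha * I_vals)
    return QuboMatrix(q, alpha=alpha, provenance={"importance": I_vals, "redundancy": R_vals})


def energy(Q: QuboMatrix, mask: FeatureMask | np.ndarray) -> float:
    """Evaluate ``x^T Q x`` for a binary mask (0 for the empty mask)."""
    x = mask.bits if isinstance(mask, FeatureMask) else np.asarray(mask)
    if len(x) != Q.n_features:
        raise DataError("mask length does not match the QUBO dimension")
    x = x.astype(float)
    return float(x @ Q.q @ x)


def add_cardinality_penalty(Q: QuboMatrix, k: int, M: float | None = None) -> QuboMatrix:
    """Add the k-hot penalty ``M (sum_i x_i - k)^2`` in QUBO form.

    Expanding the square gives ``diagonal += M (1 - 2k)`` and
    ``upper off-diagonal += 2M``; the constant ``M k^2`` is dropped, so
    penalized energies are offset by ``-M k^2`` relative to the literal
    square but the minimizers are unchanged.  For sufficiently large ``M``
    every global minimizer has exactly ``k`` bits set.  The default
    magnitude ``M = 2 n max|Q|`` is a standard sufficient scale.
    """
    n = Q.n_features
    if not 1 <= k <= n:
        raise InvalidParameterError(f"k must lie in 1..{n}, got {k}")
    if M is None:
        M = 2.0 * n * float(np.abs(Q.q).max()) or 1.0
    if M <= 0:
        raise InvalidParameterError(f"penalty magnitude M must be positive, got {M}")
    q = Q.q.copy()
    q[np.triu_indices(n, k=1)] += 2.0 * M
    q[np.diag_indices(n)] += M * (1.0 - 2.0 * k)
    prov = dict(Q.provenance, penalty={"k": k, "M": M})
    return QuboMatrix(q, alpha=Q.alpha, provenance=prov)


def rank_by_contribution(
    Q: QuboMatrix, mask: FeatureMask, extend_to: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy energy-contribution ordering of selected features.

    Repeatedly emits the not-yet-emitted selected feature whose addition
    to the emitted set most decreases the energy; the cumulative sum of
    the per-feature deltas reproduces ``energy(Q, mask)`` exactly.

    When ``extend_to`` exceeds the mask size the ordering continues
    greedily over the *unselected* features, so a ranking of any depth can
    be produced even when the unconstrained minimizer holds fewer bits —
    selected features are always exhausted first.

    Returns
    -------
    order : ndarray
        1-based feature indices in contribution order.
    deltas : ndarray
        Energy change contributed by each feature when it was added.
    """
    if mask.n_selected == 0:
        raise InvalidParameterError("mask must select at least one feature")
    if len(mask) != Q.n_features:
        raise DataError("mask length does not match the QUBO dimension")
    depth = mask.n_selected if extend_to is None else int(extend_to)
    if depth > Q.n_features:
        raise InvalidParameterError("ranking depth exceeds the number of features")

    diag = Q.diagonal()
    S = Q.symmetric_offdiag()
    in_mask = mask.bits.astype(bool)
    emitted = np.zeros(Q.n_features, dtype=bool)
    coupling = np.zeros(Q.n_features)  # sum of S to the emitted set
    order, deltas = [], []
    for _ in range(depth):
        pool = in_mask & ~emitted
        if not pool.any():
            pool = ~emitted
        delta = np.where(pool, diag + coupling, np.inf)
        nxt = int(np.argmin(delta))  # first index wins ties -> deterministic
        order.append(nxt + 1)
        deltas.append(delta[nxt])
        emitted[nxt] = True
        coupling += S[:, nxt]
    return np.asarray(order, dtype=np.int64), np.asarray(deltas)


def energy_path(Q: QuboMatrix, ordering: Sequence[int]) -> np.ndarray:
    """Cumulative energies of the growing prefixes of an ordered feature list.

    Element ``m`` is the energy of the mask holding the first ``m + 1``
    features of ``ordering`` (1-based indices).
    """
    idx = np.asarray(list(ordering), dtype=np.int64)
    if len(idx) == 0:
        raise InvalidParameterError("ordering must be non-empty")
    if idx.min() < 1 or idx.max() > Q.n_features:
        raise InvalidParameterError("ordering indices must lie in 1..n_features")
    if len(np.unique(idx)) != len(idx):
        raise InvalidParameterError("ordering contains a duplicate index")
    diag = Q.diagonal()
    S = Q.symmetric_offdiag()
    coupling = np.zeros(Q.n_features)
    out = np.empty(len(idx))
    total = 0.0
    for m, i1 in enumerate(idx):
        i = i1 - 1
        total += diag[i] + coupling[i]
        out[m] = total
        coupling += S[:, i]
    return out


# ---------------------------------------------------------------------------
# coordinate text interchange (i, j, value per line, 1-based, upper triangle)
# ---------------------------------------------------------------------------


def to_coo_text(Q: QuboMatrix) -> str:
    lines = [f"# qubo n={Q.n_features} alpha={Q.alpha}"]
    ii, jj = np.nonzero(Q.q)
    for i, j in zip(ii, jj):
        lines.append(f"{i + 1} {j + 1} {float(Q.q[i, j])!r}")
    return "\n".join(lines) + "\n"


def from_coo_text(text: str) -> QuboMatrix:
    n = None
    alpha = None
    entries = []
    for line in _io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("n="):
                    n = int(tok[2:])
                elif tok.startswith("alpha=") and tok[6:] != "None":
                    alpha = float(tok[6:])
            continue
        i_s, j_s, v_s = line.split()
        entries.append((int(i_s), int(j_s), float(v_s)))
    if n is None:
        n = max(max(i, j) for i, j, _ in entries)
    q = np.zeros((n, n))
    for i, j, v in entries:
        if i > j:
            raise DataError(f"lower-triangular entry ({i}, {j}) in QUBO file")
        q[i - 1, j - 1] = v
    return QuboMatrix(q, alpha=alpha)


def save_qubo(Q: QuboMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_coo_text(Q))


def load_qubo(path) -> QuboMatrix:
    with open(path) as fh:
        return from_coo_text(fh.read())
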