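"""Quality-control filtering and Pearson-residual normalization of counts.

The count matrix is genes x cells.  Cells are filtered first (library
size, mitochondrial count fraction, detected-gene count), then genes are
filtered against the *surviving* cells — gene nonzero counts depend on
which cells remain, so the order matters and is fixed here.  "Minimum"
thresholds are inclusive: a cell with exactly the minimum library size
passes.  A removed cell is attributed to the first criterion it fails
(library size, then mitochondrial fraction, then detected genes) so the
report counts add up to the number of cells removed.

The Pearson residual of count ``x_gc`` is ``(x - mu) / sqrt(mu + mu^2 /
theta)`` with ``mu`` the product of row and column sums over the grand
total — the expected count under a constant-expression null — and
``theta`` the negative-binomial inverse overdispersion (default 100, the
standard analytic-residual choice; ``theta -> inf`` recovers the
classical Poisson residual).  Residuals are clipped to ``±sqrt(n_cells)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, EmptyResultError

DEFAULT_MITO_PREFIXES = ("MT-", "mt-")
DEFAULT_THETA = 100.0


@dataclass
class CountMatrix:
    """Raw counts, genes x cells, with name vectors and a mito flag."""

    counts: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise DataError("count matrix must be 2-D (genes x cells)")
        if np.any(counts < 0):
            raise DataError("counts must be nonnegative")
        if len(self.gene_names) != counts.shape[0]:
            raise DataError("gene name count does not match matrix rows")
        if len(self.cell_names) != counts.shape[1]:
            raise DataError("cell name count does not match matrix columns")
        self.counts = counts

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def mito_flag(self) -> np.ndarray:
        return np.array(
            [any(g.startswith(p) for p in self.mito_prefixes) for g in self.gene_names]
        )


@dataclass
class FilterReport:
    """Per-criterion removal counts from one qc_filter pass."""

    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    removed_low_library: int = 0
    removed_high_mito: int = 0
    removed_few_genes: int = 0
    removed_rare_genes: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def cells_removed(self) -> int:
        return self.removed_low_library + self.removed_high_mito + self.removed_few_genes

    @property
    def genes_removed(self) -> int:
        return self.removed_rare_genes

    def to_dict(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_out": self.cells_out,
            "genes_in": self.genes_in,
            "genes_out": self.genes_out,
            "removed_low_library": self.removed_low_library,
            "removed_high_mito": self.removed_high_mito,
            "removed_few_genes": self.removed_few_genes,
            "removed_rare_genes": self.removed_rare_genes,
            "thresholds": self.thresholds,
        }


def qc_filter(
    M: CountMatrix,
    min_reads_per_cell: int = 1000,
    max_mito_frac: float = 0.15,
    min_cells_per_gene: int = 15,
    min_genes_per_cell: int = 500,
) -> tuple[CountMatrix, FilterReport]:
    """Remove failing cells, then genes rare among the surviving cells.

    A gene must be nonzero in at least ``min_cells_per_gene`` surviving
    cells (strictly fewer -> removed).  Raises
    :class:`~qubofs.errors.EmptyResultError` when no cell survives.
    """
    counts = M.counts
    lib = counts.sum(axis=0)
    mito = M.mito_flag
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, counts[mito].sum(axis=0) / np.maximum(lib, 1), 1.0)
    genes_detected = (counts > 0).sum(axis=0)

    fail_lib = lib < min_reads_per_cell
    fail_mito = mito_frac > max_mito_frac
    fail_genes = genes_detected < min_genes_per_cell
    keep_cells = ~(fail_lib | fail_mito | fail_genes)
    if not keep_cells.any():
        raise EmptyResultError("qc_filter removed every cell")

    # attribute each removed cell to the first criterion it fails
    n_lib = int(fail_lib.sum())
    n_mito = int((fail_mito & ~fail_lib).sum())
    n_few = int((fail_genes & ~fail_lib & ~fail_mito).sum())

    sub = counts[:, keep_cells]
    keep_genes = (sub > 0).sum(axis=1) >= min_cells_per_gene
    out = CountMatrix(
        sub[keep_genes],
        [g for g, k in zip(M.gene_names, keep_genes) if k],
        [c for c, k in zip(M.cell_names, keep_cells) if k],
        mito_prefixes=M.mito_prefixes,
    )
    report = FilterReport(
        cells_in=M.n_cells,
        cells_out=out.n_cells,
        genes_in=M.n_genes,
        genes_out=out.n_genes,
        removed_low_library=n_lib,
        removed_high_mito=n_mito,
        removed_few_genes=n_few,
        removed_rare_genes=int((~keep_genes).sum()),
        thresholds={
            "min_reads_per_cell": min_reads_per_cell,
            "max_mito_frac": max_mito_frac,
            "min_cells_per_gene": min_cells_per_gene,
            "min_genes_per_cell": min_genes_per_cell,
        },
    )
    return out, report


def pearson_residuals(M: CountMatrix, theta: float = DEFAULT_THETA):
    """Analytic Pearson residuals, returned cells x genes.

    Run :func:`qc_filter` first so there are no all-zero rows or columns.
    Returns a :class:`pandas.DataFrame` indexed by cell with gene columns,
    ready to feed the selection pipeline.
    """
    import pandas as pd

    counts = M.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise DataError("count matrix has zero grand total")
    mu = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    resid = (counts - mu) / np.sqrt(mu + mu**2 / theta)
    clip = np.sqrt(M.n_cells)
    resid = np.clip(resid, -clip, clip)
    if not np.all(np.isfinite(resid)):
        raise DataError("non-finite residuals; run qc_filter before transforming")
    return pd.DataFrame(resid.T, index=list(M.cell_names), columns=list(M.gene_names))
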