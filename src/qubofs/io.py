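"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as dense CSV/TSV (cells as rows, header row of
feature names) or MatrixMarket ``.mtx`` with one-name-per-line sidecar
files; targets are one-column headerless text, one value per cell in row
order.  Count matrices for preprocessing are genes x cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io

from .errors import DataError
from .preprocess import CountMatrix


def _read_names(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_expression(path, features_path=None, cells_path=None) -> pd.DataFrame:
    """Load a cells x features expression matrix as a DataFrame."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy_io.mmread(path)
        mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        columns = _read_names(features_path) if features_path else None
        index = _read_names(cells_path) if cells_path else None
        df = pd.DataFrame(mat, columns=columns, index=index)
    else:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise DataError(f"no data in {path}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    sep = "\t" if Path(path).suffix in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def read_target(path) -> np.ndarray:
    values = np.loadtxt(path, dtype=float, ndmin=1)
    if values.ndim != 1:
        raise DataError("target file must hold a single column")
    return values


def write_target(y, path) -> None:
    np.savetxt(path, np.asarray(y, dtype=float), fmt="%.10g")


def read_counts(path, genes_path=None, cells_path=None, **kwargs) -> CountMatrix:
    """Load a genes x cells raw count matrix (.mtx + sidecars, or dense CSV)."""
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise DataError("MatrixMarket counts need gene and cell name sidecar files")
        mat = scipy_io.mmread(path)
        counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        genes = _read_names(genes_path)
        cells = _read_names(cells_path)
    else:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy()
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    return CountMatrix(counts, genes, cells, **kwargs)


def write_counts(M: CountMatrix, path, genes_path=None, cells_path=None) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy import sparse

        scipy_io.mmwrite(path, sparse.coo_matrix(M.counts))
        if genes_path:
            Path(genes_path).write_text("\n".join(M.gene_names) + "\n")
        if cells_path:
            Path(cells_path).write_text("\n".join(M.cell_names) + "\n")
    else:
        pd.DataFrame(M.counts, index=M.gene_names, columns=M.cell_names).to_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
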