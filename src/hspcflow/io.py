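"""Readers and writers for the on-disk formats.

Count matrices live in 10X-style directories: ``matrix.mtx`` (Matrix
Market coordinate integer, rows = genes, 1-based indices per the
standard), ``genes.tsv`` (two columns, id and symbol) or ``features.tsv``
(three-column dialect), ``barcodes.tsv``, and an optional ``cells.tsv``
with per-cell metadata (first column barcode).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DataError
from .matrix import UmiMatrix

__all__ = ["read_counts_dir", "write_counts_dir", "write_manifest"]

MATRIX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
CELLS_FILE = "cells.tsv"


def _read_names(path: Path, what: str) -> list:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    return [ln.split("\t") for ln in lines], what


def read_counts_dir(path) -> UmiMatrix:
    """Read a counts directory into a :class:`UmiMatrix`.

    ``genes.tsv`` may have one or two columns (id, symbol) and the
    three-column ``features.tsv`` dialect is also accepted; the symbol
    column is used as the gene name. Non-integer or negative matrix
    entries, dimension mismatches and duplicate barcodes are errors.
    """
    path = Path(path)
    mtx_path = path / MATRIX_FILE
    if not mtx_path.exists():
        raise DataError(f"{mtx_path} not found")
    mat = scipy.io.mmread(mtx_path)
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise DataError(f"{mtx_path}: non-integer counts")
        mat = mat.astype(np.int64)
    if mat.data.size and mat.data.min() < 0:
        raise DataError(f"{mtx_path}: negative counts")

    genes_path = path / "genes.tsv"
    if not genes_path.exists():
        genes_path = path / "features.tsv"
    if not genes_path.exists():
        raise DataError(f"{path}: neither genes.tsv nor features.tsv found")
    rows, _ = _read_names(genes_path, "genes")
    # 1 column: name; 2 columns: id, symbol; 3 columns (features dialect):
    # id, name, feature type -> use the second field when present.
    genes = [r[1] if len(r) >= 2 else r[0] for r in rows]

    barcodes_path = path / BARCODES_FILE
    if not barcodes_path.exists():
        raise DataError(f"{barcodes_path} not found")
    brows, _ = _read_names(barcodes_path, "barcodes")
    barcodes = [r[0] for r in brows]
    if len(set(barcodes)) != len(barcodes):
        raise DataError(f"{barcodes_path}: duplicate barcodes")

    n_genes, n_cells = mat.shape
    if len(genes) != n_genes or len(barcodes) != n_cells:
        raise DataError(
            f"{path}: matrix is {n_genes}x{n_cells} but found "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )

    cell_meta = None
    cells_path = path / CELLS_FILE
    if cells_path.exists():
        cell_meta = pd.read_csv(cells_path, sep="\t", index_col=0)
    return UmiMatrix(counts=sp.csc_matrix(mat), genes=genes,
                     barcodes=barcodes, cell_meta=cell_meta)


def write_counts_dir(matrix: UmiMatrix, path, force: bool = False) -> None:
    """Write ``matrix`` as matrix.mtx + genes.tsv + barcodes.tsv (+
    cells.tsv when metadata is present).

    Refuses to write into an existing non-empty directory unless
    ``force``.
    """
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not force:
        raise DataError(f"{path} exists and is not empty (use force=True)")
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / MATRIX_FILE, matrix.counts.tocoo(), field="integer")
    with open(path / "genes.tsv", "w") as fh:
        for g in matrix.genes:
            fh.write(f"{g}\t{g}\n")
    with open(path / BARCODES_FILE, "w") as fh:
        for b in matrix.barcodes:
            fh.write(f"{b}\n")
    if matrix.cell_meta.shape[1]:
        matrix.cell_meta.to_csv(path / CELLS_FILE, sep="\t")


def write_manifest(path, manifest: dict) -> None:
    """Serialize the run manifest (parameters, seeds, stage counts) as JSON."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
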