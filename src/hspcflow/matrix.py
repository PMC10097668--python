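"""Sparse UMI count matrix container.

Counts are stored genes x cells (rows = genes, columns = cell barcodes),
the orientation used throughout the package and in the on-disk Matrix
Market layout. Per-cell metadata (condition, genotype, niche, QC flags)
travels with the matrix as a DataFrame indexed by barcode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataError

__all__ = ["UmiMatrix"]


def _as_str_array(values, what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=object)
    if arr.ndim != 1:
        raise DataError(f"{what} must be one-dimensional")
    if len(set(arr)) != len(arr):
        raise DataError(f"duplicate {what} are not allowed")
    return arr


@dataclass
class UmiMatrix:
    """Integer gene x cell UMI count matrix with names and cell metadata.

    Parameters
    ----------
    counts
        Sparse (or dense, converted) non-negative integer matrix of shape
        ``(n_genes, n_cells)``.
    genes, barcodes
        Unique row / column names.
    cell_meta
        Optional per-cell metadata indexed by barcode; reindexed to the
        barcode order of the matrix.
    """

    counts: sp.csc_matrix
    genes: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csc_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsc()
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and not np.allclose(data, np.round(data)):
                raise DataError("UMI counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.data.size and self.counts.data.min() < 0:
            raise DataError("UMI counts must be non-negative")
        self.counts.eliminate_zeros()
        self.genes = _as_str_array(self.genes, "gene names")
        self.barcodes = _as_str_array(self.barcodes, "barcodes")
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise DataError(
                f"{len(self.genes)} gene names for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells:
            raise DataError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        else:
            missing = set(self.barcodes) - set(self.cell_meta.index)
            if missing:
                raise DataError(
                    f"cell_meta is missing {len(missing)} barcodes "
                    f"(e.g. {sorted(missing)[:3]})"
                )
            self.cell_meta = self.cell_meta.loc[list(self.barcodes)].copy()
            self.cell_meta.index.name = "barcode"
        self._gene_index = None

    # -- basic geometry ------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_index(self) -> dict:
        """Mapping gene name -> row number (built lazily)."""
        if self._gene_index is None:
            self._gene_index = {g: i for i, g in enumerate(self.genes)}
        return self._gene_index

    # -- core operations -----------------------------------------------

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(np.int64)

    def gene_rows(self, names) -> np.ndarray:
        """Row indices for ``names``; raises naming the first absent gene."""
        idx = self.gene_index
        rows = []
        for name in names:
            if name not in idx:
                raise DataError(f"gene {name!r} not present in matrix")
            rows.append(idx[name])
        return np.asarray(rows, dtype=np.int64)

    def subset_cells(self, selector) -> "UmiMatrix":
        """New matrix restricted to the selected columns (mask or indices)."""
        selector = np.asarray(selector)
        if selector.dtype == bool:
            if selector.size != self.n_cells:
                raise DataError("boolean cell selector has wrong length")
            idx = np.flatnonzero(selector)
        else:
            idx = selector.astype(np.int64)
        return UmiMatrix(
            counts=self.counts[:, idx],
            genes=self.genes,
            barcodes=self.barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def equals(self, other: "UmiMatrix") -> bool:
        return (
            np.array_equal(self.genes, other.genes)
            and np.array_equal(self.barcodes, other.barcodes)
            and (self.counts != other.counts).nnz == 0
        )
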