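"""Cell quality filtering.

Three rules, applied in fixed priority order so every removed cell has
exactly one reason:

1. floor — cells with *more than* ``min_umi`` total UMIs are kept
   (default 450, a strict lower bound aimed at empty wells);
2. top percentile — among floor survivors, cells strictly above the
   ``(100 - top_pct)`` linear-interpolation percentile of survivor
   totals are removed (default top 3%, aimed at doublets); the
   percentile is computed after the floor so empty wells cannot drag
   it down;
3. mitochondrial — remaining cells with a mitochondrial UMI fraction
   above ``mito_max_frac`` are removed (default 0.20; damaged cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyResultError
from .matrix import UmiMatrix

__all__ = ["QcParams", "QcReport", "cell_totals", "filter_cells"]


@dataclass(frozen=True)
class QcParams:
    min_umi: int = 450
    top_pct: float = 3.0
    mito_max_frac: float = 0.20
    mito_prefix: str = "mt-"
    mito_genes: tuple | None = None  # explicit list overrides the prefix

    def __post_init__(self):
        if not (0 <= self.top_pct < 100):
            raise ConfigError("top_pct must be in [0, 100)")
        if not (0 < self.mito_max_frac <= 1):
            raise ConfigError("mito_max_frac must be in (0, 1]")
        if self.min_umi < 0:
            raise ConfigError("min_umi must be non-negative")


@dataclass
class QcReport:
    """Counts per disposition plus the per-cell table.

    ``disposition`` is indexed by barcode with columns ``total``,
    ``mito_frac`` and ``status`` in {kept, low, top, mito}. The counts
    always satisfy n_input = n_kept + n_removed_low + n_removed_top +
    n_removed_mito.
    """

    n_input: int
    n_kept: int
    n_removed_low: int
    n_removed_top: int
    n_removed_mito: int
    top_cutoff: float
    disposition: pd.DataFrame


def cell_totals(matrix: UmiMatrix) -> np.ndarray:
    """Per-cell total UMI counts (column sums)."""
    return matrix.cell_totals()


def filter_cells(matrix: UmiMatrix, params: QcParams = QcParams()) -> tuple:
    """Apply the floor / top-percentile / mito rules; return
    ``(filtered_matrix, QcReport)``.

    Raises :class:`EmptyResultError` if no cell survives.
    """
    if matrix.n_cells == 0:
        raise EmptyResultError("input matrix has no cells")
    totals = matrix.cell_totals()

    low = totals <= params.min_umi
    survivors = totals[~low]
    if survivors.size == 0:
        raise EmptyResultError(
            f"all {matrix.n_cells} cells fall at or below {params.min_umi} UMIs"
        )
    if params.top_pct > 0:
        cutoff = float(np.percentile(survivors, 100.0 - params.top_pct,
                                     method="linear"))
    else:
        cutoff = float(survivors.max())
    top = (~low) & (totals > cutoff)

    if params.mito_genes is not None:
        mito_rows = matrix.gene_rows(params.mito_genes)
    else:
        mito_rows = np.flatnonzero(
            np.char.startswith(matrix.genes.astype(str), params.mito_prefix)
        )
    if mito_rows.size:
        mito_counts = np.asarray(matrix.counts[mito_rows].sum(axis=0)).ravel()
    else:
        mito_counts = np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    mito = (~low) & (~top) & (mito_frac > params.mito_max_frac)

    keep = ~(low | top | mito)
    if not keep.any():
        raise EmptyResultError("quality filtering removed every cell")

    status = np.full(matrix.n_cells, "kept", dtype=object)
    status[mito] = "mito"
    status[top] = "top"
    status[low] = "low"
    disposition = pd.DataFrame(
        {"total": totals, "mito_frac": mito_frac, "status": status},
        index=pd.Index(matrix.barcodes, name="barcode"),
    )
    report = QcReport(
        n_input=matrix.n_cells,
        n_kept=int(keep.sum()),
        n_removed_low=int(low.sum()),
        n_removed_top=int(top.sum()),
        n_removed_mito=int(mito.sum()),
        top_cutoff=cutoff,
        disposition=disposition,
    )
    return matrix.subset_cells(keep), report
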