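"""Cell-type composition tables and exact tests on type abundance.

The central question is whether a focal cell type (HSCs) is over- or
under-represented in one condition versus another. Each comparison
collapses the composition table to a 2x2 contingency table (focal vs all
other types x condition A vs condition B) and applies a two-sided Fisher
exact test; fold changes are ratios of the focal fractions, with a
Haldane +0.5 correction when a zero cell occurs. Multiple comparisons
are adjusted with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotate import UNKNOWN, CellAnnotation
from .errors import DataError

__all__ = [
    "CompositionTable",
    "AbundanceResult",
    "composition_table",
    "fisher_exact_2x2",
    "compare_type_abundance",
    "compare_abundances",
]


@dataclass
class CompositionTable:
    """Cell type x condition count matrix with derived fractions."""

    counts: pd.DataFrame  # rows = cell types, columns = condition labels

    def __post_init__(self):
        if (self.counts.sum(axis=0) == 0).any():
            empty = self.counts.columns[self.counts.sum(axis=0) == 0]
            raise DataError(f"conditions with no cells: {list(empty)}")

    @property
    def fractions(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)


@dataclass
class AbundanceResult:
    focal_type: str
    cond_a: str
    cond_b: str
    fraction_a: float
    fraction_b: float
    fold: float
    table: np.ndarray  # 2x2 [[a, colA-a], [b, colB-b]]
    p: float
    q: float | None = None


def composition_table(annotation: CellAnnotation, metadata) -> CompositionTable:
    """Cross-tabulate cell type x condition.

    ``metadata`` is a per-cell condition Series (indexed by barcode) or a
    DataFrame with a ``condition`` column. Cells lacking a condition are
    an error listing the offending barcodes.
    """
    if isinstance(metadata, pd.DataFrame):
        if "condition" not in metadata.columns:
            raise DataError("metadata must have a 'condition' column")
        condition = metadata["condition"]
    else:
        condition = pd.Series(metadata)
    labels = annotation.cells["cell_type"]
    cond = condition.reindex(labels.index)
    missing = cond.index[cond.isna()]
    if len(missing):
        raise DataError(
            f"{len(missing)} cells lack a condition label "
            f"(e.g. {list(missing[:5])})"
        )
    counts = pd.crosstab(labels, cond)
    counts.index.name = "cell_type"
    counts.columns.name = "condition"
    return CompositionTable(counts=counts)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Point-probability rule: p is the sum of hypergeometric probabilities
    of every table with the same margins whose probability does not
    exceed that of the observed table (with a relative 1e-12 slack for
    floating-point ties). A table with a zero margin has a single
    attainable configuration, so p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DataError("fisher_exact_2x2 expects a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or not np.allclose(t, np.round(t)):
            raise DataError("table entries must be non-negative integers")
        t = np.round(t).astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def compare_type_abundance(table: CompositionTable, focal_type: str,
                           cond_a: str, cond_b: str,
                           include_unknown: bool = False) -> AbundanceResult:
    """Fisher test of focal-type abundance between two conditions.

    Unknown-labelled cells are excluded from the "all other" pool unless
    ``include_unknown``; fold is (frac_a / frac_b), Haldane-corrected
    (+0.5 per cell) when any 2x2 entry is zero.
    """
    counts = table.counts
    if focal_type not in counts.index:
        raise DataError(f"focal type {focal_type!r} absent from composition table")
    for cond in (cond_a, cond_b):
        if cond not in counts.columns:
            raise DataError(f"condition {cond!r} absent from composition table")
    rows = counts.index if include_unknown else counts.index[counts.index != UNKNOWN]
    if focal_type == UNKNOWN and not include_unknown:
        raise DataError("cannot test the Unknown type while excluding it")
    sub = counts.loc[rows]
    a = int(sub.loc[focal_type, cond_a])
    b = int(sub.loc[focal_type, cond_b])
    col_a = int(sub[cond_a].sum())
    col_b = int(sub[cond_b].sum())
    t = np.array([[a, col_a - a], [b, col_b - b]], dtype=np.int64)
    frac_a = a / col_a if col_a else float("nan")
    frac_b = b / col_b if col_b else float("nan")
    if (t == 0).any():
        fold = ((a + 0.5) / (col_a + 1.0)) / ((b + 0.5) / (col_b + 1.0))
    else:
        fold = frac_a / frac_b
    return AbundanceResult(
        focal_type=focal_type, cond_a=cond_a, cond_b=cond_b,
        fraction_a=frac_a, fraction_b=frac_b, fold=float(fold),
        table=t, p=fisher_exact_2x2(t),
    )


def compare_abundances(table: CompositionTable, focal_type: str, pairs,
                       include_unknown: bool = False) -> list:
    """Run :func:`compare_type_abundance` for each (cond_a, cond_b) pair
    and BH-adjust the p-values across the batch."""
    from .signatures import bh_adjust

    results = [
        compare_type_abundance(table, focal_type, a, b, include_unknown)
        for a, b in pairs
    ]
    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results
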