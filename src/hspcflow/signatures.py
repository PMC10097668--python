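"""Fixed-depth gene-set scores and group comparisons.

A cell's signature score for a gene set is the plain sum of its UMI
counts over the set's genes *after* the whole matrix has been
downsampled to a common depth (default 750 UMIs per cell). Fixing the
depth removes library-size bias from the sum without any per-gene
scaling, at the cost of discarding counts — the convention this package
follows. Cells whose total is already at or below the depth are kept
unchanged and flagged; they are excluded from group comparisons by
default, since their scores live on a different scale.

Group comparisons use the two-sided Wilcoxon rank-sum test (exact
enumeration for small tie-free groups, normal approximation with tie and
continuity corrections otherwise) with Benjamini-Hochberg adjustment
across the whole batch of (set x condition-pair) tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ConfigError, DataError
from .genesets import GeneSet, GeneSetCollection
from .matrix import UmiMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "ScoreComparisonResult",
    "downsample",
    "exclusive_sets",
    "score_cells",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "compare_scores",
]

DEFAULT_DEPTH = 750


def downsample(matrix: UmiMatrix, depth: int = DEFAULT_DEPTH,
               seed: int = 0) -> UmiMatrix:
    """Subsample each cell to exactly ``depth`` UMIs without replacement.

    Cells with more than ``depth`` UMIs get a uniform random subset of
    exactly ``depth`` of their UMIs (a multivariate hypergeometric draw
    across genes); cells at or below ``depth`` are returned unchanged and
    flagged in ``cell_meta['below_depth']``. Deterministic given ``seed``.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    csc = matrix.counts.tocsc()
    totals = matrix.cell_totals()
    indptr, indices, data = csc.indptr, csc.indices, csc.data
    new_data = data.copy()
    for j in range(matrix.n_cells):
        if totals[j] <= depth:
            continue
        sl = slice(indptr[j], indptr[j + 1])
        new_data[sl] = rng.multivariate_hypergeometric(data[sl], depth)
    out = csc.copy()
    out.data = new_data
    meta = matrix.cell_meta.copy()
    meta["below_depth"] = totals <= depth
    return UmiMatrix(counts=out, genes=matrix.genes,
                     barcodes=matrix.barcodes, cell_meta=meta)


def exclusive_sets(collection: GeneSetCollection, minuend: str,
                   subtrahend: str) -> GeneSet:
    """Set difference ``minuend \\ subtrahend`` (name suffixed ``_excl``).

    This is the shared-gene reanalysis device: scoring the IFN-alpha set
    without its IFN-gamma-overlapping genes isolates signal specific to
    the minuend pathway. An empty result is an error — the sum score is
    undefined on an empty set.
    """
    m, s = collection[minuend], collection[subtrahend]
    removed = set(s.genes)
    genes = tuple(g for g in m.genes if g not in removed)
    if not genes:
        raise DataError(
            f"{minuend!r} minus {subtrahend!r} leaves no genes to score"
        )
    return GeneSet(name=f"{minuend}_excl", genes=genes,
                   description=f"{minuend} without {subtrahend} genes")


@dataclass
class ScoreTable:
    """Per-cell integer scores for each gene set.

    ``scores`` is cells x sets (indexed by barcode); ``condition`` and
    ``below_depth`` are aligned per-cell series; ``depth`` records the
    downsampling depth the scores were computed at.
    """

    scores: pd.DataFrame
    condition: pd.Series
    below_depth: pd.Series
    depth: int


@dataclass
class ScoreComparisonResult:
    set_name: str
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    statistic: float
    p: float
    q: float | None = None


def score_cells(ds_matrix: UmiMatrix, sets: GeneSetCollection,
                depth: int = DEFAULT_DEPTH) -> ScoreTable:
    """Sum downsampled counts over each set's genes, per cell.

    Genes in a set but absent from the matrix contribute 0 and are
    logged once per set; a set with no gene present is an error.
    """
    if len(sets) == 0:
        raise ConfigError("no gene sets to score")
    gi = ds_matrix.gene_index
    csr = ds_matrix.counts.tocsr()
    columns = {}
    for s in sets:
        present = [gi[g] for g in s.genes if g in gi]
        n_missing = len(s.genes) - len(present)
        if not present:
            raise DataError(f"no gene of set {s.name!r} is present in the matrix")
        if n_missing:
            log.warning("set %s: %d of %d genes absent from matrix",
                        s.name, n_missing, len(s.genes))
        columns[s.name] = np.asarray(
            csr[np.asarray(present)].sum(axis=0)
        ).ravel().astype(np.int64)
    scores = pd.DataFrame(columns, index=pd.Index(ds_matrix.barcodes, name="barcode"))
    meta = ds_matrix.cell_meta
    condition = (meta["condition"] if "condition" in meta.columns
                 else pd.Series("all", index=scores.index))
    below = (meta["below_depth"].astype(bool) if "below_depth" in meta.columns
             else pd.Series(ds_matrix.cell_totals() <= depth, index=scores.index))
    return ScoreTable(scores=scores, condition=condition,
                      below_depth=below, depth=depth)


# -- rank-sum test ----------------------------------------------------


def _exact_ranksum_p(w_obs: float, nx: int, ny: int) -> float:
    """Exact two-sided p for the rank-sum W of x (tie-free ranks 1..N):
    distribution of W over all C(N, nx) equally likely subsets, computed
    by subset-sum dynamic programming."""
    n_tot = nx + ny
    # table[j][s] = number of j-subsets of {1..r} summing to s, built rank by rank
    max_sum = n_tot * (n_tot + 1) // 2
    table = np.zeros((nx + 1, max_sum + 1), dtype=np.float64)
    table[0, 0] = 1.0
    for r in range(1, n_tot + 1):
        for j in range(min(r, nx), 0, -1):
            table[j, r:] += table[j - 1, : max_sum - r + 1]
    counts = table[nx]
    total = counts.sum()
    mu = nx * (n_tot + 1) / 2.0
    dev = abs(w_obs - mu)
    sums = np.arange(max_sum + 1)
    tail = counts[np.abs(sums - mu) >= dev - 1e-9].sum()
    return float(tail / total)


def wilcoxon_rank_sum(x, y) -> tuple:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    Exact enumeration is used when both groups have at most 8
    observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:nx].sum())
    u = w - nx * (nx + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if max(nx, ny) <= 8 and not has_ties:
        return u, _exact_ranksum_p(w, nx, ny)

    n_tot = nx + ny
    mu = nx * ny / 2.0
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    sigma2 = nx * ny / 12.0 * ((n_tot + 1) - tie_term / (n_tot * (n_tot - 1)))
    if sigma2 <= 0:
        return u, 1.0  # every observation tied
    z = max(0.0, (abs(u - mu) - 0.5)) / np.sqrt(sigma2)
    # keep p strictly positive even when the normal tail underflows
    p = max(float(2.0 * norm.sf(z)), 1e-300)
    return u, min(1.0, p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q(i) = min over j >= i (in sorted order) of m * p(j) / j, capped at
    1 and mapped back to the input order. All p must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("bh_adjust expects a non-empty 1-d p-value list")
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def compare_scores(scores: ScoreTable, focal: str | None = None,
                   comparisons=None, include_below_depth: bool = False,
                   min_cells: int = 3) -> list:
    """Rank-sum tests of per-cell scores between condition pairs.

    ``comparisons`` is a list of (group_a, group_b) condition pairs; if
    omitted, ``focal`` is compared against every other condition. One BH
    family covers the whole batch (all sets x all pairs). Below-depth
    cells are excluded unless ``include_below_depth``.
    """
    condition = scores.condition
    if comparisons is None:
        if focal is None:
            raise ConfigError("provide either focal or explicit comparisons")
        others = [c for c in pd.unique(condition) if c != focal]
        if not others:
            raise ConfigError(f"no condition other than {focal!r} present")
        comparisons = [(focal, other) for other in others]

    mask = pd.Series(True, index=scores.scores.index)
    if not include_below_depth:
        mask &= ~scores.below_depth
    results = []
    for set_name in scores.scores.columns:
        vals = scores.scores[set_name]
        for ga, gb in comparisons:
            xa = vals[mask & (condition == ga)].to_numpy()
            xb = vals[mask & (condition == gb)].to_numpy()
            for label, arr in ((ga, xa), (gb, xb)):
                if arr.size < min_cells:
                    raise DataError(
                        f"condition {label!r} has {arr.size} usable cells "
                        f"(< {min_cells}) for set {set_name!r}"
                    )
            u, p = wilcoxon_rank_sum(xa, xb)
            results.append(ScoreComparisonResult(
                set_name=set_name, group_a=ga, group_b=gb,
                median_a=float(np.median(xa)), median_b=float(np.median(xb)),
                n_a=int(xa.size), n_b=int(xb.size), statistic=float(u), p=float(p),
            ))
    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


def comparison_frame(results) -> pd.DataFrame:
    """Tabulate a list of :class:`ScoreComparisonResult` as a DataFrame."""
    return pd.DataFrame([r.__dict__ for r in results])
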