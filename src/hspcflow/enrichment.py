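"""Preranked gene-set enrichment analysis (GSEA), from scratch.

Genes are ranked by signed log2 fold change between a focal cell group
and the rest (means on the depth-matched matrix, with a pseudocount).
For each gene set, a weighted Kolmogorov-Smirnov running sum walks the
ranked list: hits push the sum up in proportion to |metric|^p, misses
pull it down by 1/(N - |S|); the enrichment score (ES) is the signed
maximal deviation. Significance comes from a gene-label permutation
null (random same-size gene draws), with the normalized score
NES = ES / mean(|null ES| of the same sign), one-tail permutation
p-values within the sign, and BH-adjusted q across sets. Sets with
q < 0.2 are flagged significant, the conventional preranked threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genesets import GeneSet, GeneSetCollection
from .matrix import UmiMatrix
from .signatures import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "rank_by_fold_change",
    "enrichment_score",
    "gsea_preranked",
]

MIN_SET_SIZE = 5
Q_SIGNIFICANT = 0.2


@dataclass(frozen=True)
class RankedList:
    """Genes in descending metric order with their metric values."""

    genes: tuple
    metric: np.ndarray

    def __post_init__(self):
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise DataError("ranked list contains duplicate genes")
        metric = np.asarray(self.metric, dtype=float)
        if metric.shape != (len(genes),):
            raise DataError("metric length does not match gene list")
        if np.any(np.diff(metric) > 0):
            raise DataError("metric must be in descending order")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "metric", metric)

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_fold_change(ds_matrix: UmiMatrix, in_group,
                        pseudocount: float = 0.1,
                        center: str = "median") -> RankedList:
    """Rank genes by log2((mean_in + a) / (mean_out + a)).

    ``in_group`` is a boolean mask over cells (the focal group); means
    are per-gene averages over cells of each group on the supplied
    (depth-matched) matrix. Descending metric; ties broken by gene name.

    With ``center='median'`` (the default) the median log-ratio across
    genes is subtracted from every metric. Depth-matched counts are
    compositional: when a block of genes is genuinely up in the focal
    group, every *unchanged* gene acquires a spurious negative
    log-ratio, and without centering whole signal-free gene sets drift
    coherently to the bottom of the ranking. Median-of-ratios centering
    (the same idea behind DESeq-style size factors) restores unchanged
    genes to zero. ``center='none'`` gives the raw log-ratio.
    """
    mask = np.asarray(in_group, dtype=bool)
    if mask.size != ds_matrix.n_cells:
        raise DataError("in_group mask length does not match the matrix")
    if not mask.any() or mask.all():
        raise DataError("both the focal group and its complement must be non-empty")
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    if center not in ("median", "none"):
        raise ConfigError("center must be 'median' or 'none'")
    csr = ds_matrix.counts.tocsr()
    mean_in = np.asarray(csr[:, mask].mean(axis=1)).ravel()
    mean_out = np.asarray(csr[:, ~mask].mean(axis=1)).ravel()
    metric = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
    if center == "median":
        metric = metric - np.median(metric)
    genes = ds_matrix.genes
    order = np.lexsort((genes, -metric))
    return RankedList(genes=tuple(genes[order]), metric=metric[order])


def _es_from_steps(hit_mask: np.ndarray, weights: np.ndarray) -> tuple:
    """Running sum and signed-max-deviation ES for one hit mask."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit metrics are exactly zero: fall back to unweighted hits
        hit_w = hit_mask.astype(float)
        denom = float(n_hits)
    steps = hit_w / denom - (~hit_mask) / float(n - n_hits)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def enrichment_score(ranked: RankedList, gene_set: GeneSet,
                     exponent: float = 1.0) -> tuple:
    """Weighted-KS enrichment score of ``gene_set`` in ``ranked``.

    Returns ``(ES, running_profile)``. The set must be a non-empty
    proper subset of the ranked genes. With ``exponent`` 0 the statistic
    reduces to the classic KS distance between hit positions and the
    uniform distribution.
    """
    genes = ranked.genes
    members = set(gene_set.genes)
    hit_mask = np.fromiter((g in members for g in genes), dtype=bool,
                           count=len(genes))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise DataError(f"set {gene_set.name!r} has no gene in the ranked list")
    if n_hits == len(genes):
        raise DataError(f"set {gene_set.name!r} covers the whole ranked list")
    weights = np.abs(ranked.metric) ** exponent
    es, running, _ = _es_from_steps(hit_mask, weights)
    return es, running


def _leading_edge(hit_mask: np.ndarray, running: np.ndarray, es: float) -> int:
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        return int(hit_mask[: peak + 1].sum())
    return int(hit_mask[peak:].sum())


def gsea_preranked(ranked: RankedList, collection: GeneSetCollection,
                   n_perm: int = 1000, seed: int = 0,
                   exponent: float = 1.0,
                   min_size: int = MIN_SET_SIZE) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    Null ES per set come from ``n_perm`` random same-size gene draws
    from the ranked universe (seeded, hence deterministic). Per set:
    NES = ES / mean(|null ES| same sign), p = (1 + #{same-sign null
    |ES| >= |ES|}) / (1 + #same-sign null), q = BH across sets,
    significant = q < 0.2. Sets with fewer than ``min_size`` genes in
    the ranked list are skipped with a warning.
    """
    if len(collection) == 0:
        raise ConfigError("empty gene-set collection")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    genes = ranked.genes
    n = len(genes)
    members_idx = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for s in collection:
        idx = np.asarray([gene_pos[g] for g in s.genes if g in gene_pos])
        if idx.size < min_size:
            log.warning("skipping set %s: only %d of %d genes in ranked list",
                        s.name, idx.size, len(s.genes))
            continue
        if idx.size == n:
            raise DataError(f"set {s.name!r} covers the whole ranked list")
        members_idx[s.name] = idx
    if not members_idx:
        raise DataError("no gene set passes the minimum-size filter")

    weights = np.abs(ranked.metric) ** exponent
    rng = np.random.default_rng(seed)
    rows = []
    null_cache = {}
    for name, idx in members_idx.items():
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es, running, _ = _es_from_steps(hit, weights)
        size = idx.size
        if size not in null_cache:
            null_cache[size] = _null_es(weights, n, size, n_perm, rng)
        null = null_cache[size]
        same_sign = null[null >= 0] if es >= 0 else -null[null < 0]
        p = (1.0 + (same_sign >= abs(es)).sum()) / (1.0 + same_sign.size)
        # normalize by same-sign null magnitudes; if the null never takes
        # this sign, fall back to the overall null magnitude
        denom_null = same_sign.mean() if same_sign.size else np.abs(null).mean()
        if es == 0 or denom_null == 0:
            nes = 0.0
        else:
            nes = abs(es) / denom_null * np.sign(es)
        rows.append({
            "set": name, "size": int(size), "es": es, "nes": float(nes),
            "p": float(p),
            "leading_edge_n": _leading_edge(hit, running, es),
            "n_perm": int(n_perm),
        })
    result = pd.DataFrame(rows).set_index("set")
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["q"] < Q_SIGNIFICANT
    return result


def _null_es(weights: np.ndarray, n: int, size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES distribution for random sets of ``size`` genes."""
    # random `size`-subsets via argpartition of uniform keys
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    hit = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hit, idx, True, axis=1)
    hit_w = np.where(hit, weights[None, :], 0.0)
    denom = hit_w.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    steps = hit_w / denom - (~hit) / float(n - size)
    running = np.cumsum(steps, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), peaks]
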