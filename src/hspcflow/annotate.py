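"""Cluster cells and assign HSPC cell-type labels from marker genes.

The partitioning step is a deliberately simple, fully deterministic
stand-in for graph-based metacell construction: log-normalized expression
of the most variable genes is clustered with Lloyd's algorithm started
from greedy farthest-point seeds (default k = 32, matching the
granularity of the original analysis). The biology lives in the
annotation rule, not the partitioner: each cluster is labelled by the
marker whose cross-cluster z-score is highest, with the multipotent
progenitor (MPP) label granted only when Fgd5 is elevated and no other
marker is — MPPs have no positive marker of their own beyond Fgd5, so
any other elevated lineage marker vetoes the call.

Default markers (mouse HSPC hierarchy): HSC Procr, MLP Dntt, CMP Mpo,
MegK Pf4, Ery Hba-a2, MonoP Irf8, DC Cd74, MPP Fgd5 (exclusive rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigError, DataError
from .matrix import UmiMatrix

__all__ = [
    "DEFAULT_MARKERS",
    "MarkerTable",
    "CellAnnotation",
    "normalize_log",
    "select_variable_genes",
    "cluster_cells",
    "annotate_clusters",
]

UNKNOWN = "Unknown"

#: Cell type -> marker gene, in tie-break priority order.
DEFAULT_MARKERS = {
    "HSC": "Procr",
    "MLP": "Dntt",
    "CMP": "Mpo",
    "MegK": "Pf4",
    "Ery": "Hba-a2",
    "MonoP": "Irf8",
    "DC": "Cd74",
    "MPP": "Fgd5",
}


@dataclass(frozen=True)
class MarkerTable:
    """Ordered cell-type -> marker-gene map with exclusivity rules.

    ``exclusive_types`` are assigned only when their marker is the *only*
    elevated one (the "Fgd5 and no other markers" rule for MPP).
    """

    markers: dict = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    exclusive_types: tuple = ("MPP",)

    def __post_init__(self):
        genes = list(self.markers.values())
        if len(set(genes)) != len(genes):
            raise ConfigError("marker genes must be distinct")
        if not self.markers:
            raise ConfigError("marker table is empty")
        for t in self.exclusive_types:
            if t not in self.markers:
                raise ConfigError(f"exclusive type {t!r} has no marker")

    @property
    def types(self) -> list:
        return list(self.markers)


@dataclass
class CellAnnotation:
    """Per-cell cluster ids and type labels plus per-cluster evidence.

    ``cells`` has columns ``cluster`` and ``cell_type`` indexed by
    barcode; ``clusters`` holds, per cluster, each marker's z-score and
    the assigned label.
    """

    cells: pd.DataFrame
    clusters: pd.DataFrame

    def label_of(self) -> pd.Series:
        return self.cells["cell_type"]


def normalize_log(matrix: UmiMatrix, target_sum: float = 1e4) -> pd.DataFrame:
    """Depth-normalize to ``target_sum`` UMIs per cell, then log(1+x).

    Returns a dense genes x cells DataFrame. A zero-total cell is an
    error — such cells should have been removed by QC.
    """
    totals = matrix.cell_totals().astype(float)
    if (totals == 0).any():
        bad = matrix.barcodes[totals == 0][:5]
        raise DataError(f"zero-total cells cannot be normalized: {list(bad)}")
    scaled = matrix.counts.multiply(target_sum / totals[None, :]).tocsc()
    dense = np.log1p(np.asarray(scaled.todense()))
    return pd.DataFrame(dense, index=matrix.genes, columns=matrix.barcodes)


def select_variable_genes(normalized: pd.DataFrame, n_top: int,
                          exclude=()) -> list:
    """The ``n_top`` genes with highest variance of normalized expression.

    Ties are broken by gene-name lexicographic order; genes in
    ``exclude`` (e.g. cell-cycle or stress modules) are never selected.
    """
    if n_top < 0:
        raise ConfigError("n_top must be non-negative")
    keep = normalized.index[~normalized.index.isin(set(exclude))]
    if n_top > len(keep):
        raise ConfigError(
            f"n_top={n_top} exceeds the {len(keep)} selectable genes"
        )
    variances = normalized.loc[keep].var(axis=1, ddof=0)
    order = sorted(keep, key=lambda g: (-variances[g], g))
    return order[:n_top]


def _farthest_point_seeds(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-center seeding: random first point, then iteratively the
    point farthest from its nearest chosen seed (first index on ties)."""
    n = X.shape[0]
    chosen = [int(rng.integers(n))]
    d2 = ((X - X[chosen[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
    return X[chosen].copy()


def cluster_cells(normalized: pd.DataFrame, genes, k: int = 32,
                  seed: int = 0) -> np.ndarray:
    """Lloyd-style clustering of cells on the selected-gene submatrix.

    Deterministic given ``seed``: seeds come from greedy farthest-point
    selection, then standard Lloyd iterations refine them. Returns one
    label in ``0..k-1`` per cell (column order of ``normalized``).
    """
    n_cells = normalized.shape[1]
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > n_cells:
        raise ConfigError(f"k={k} exceeds the number of cells ({n_cells})")
    missing = [g for g in genes if g not in normalized.index]
    if missing:
        raise DataError(f"genes not in matrix: {missing[:5]}")
    X = normalized.loc[list(genes)].to_numpy().T  # cells x genes
    if k == 1:
        return np.zeros(n_cells, dtype=np.int64)
    rng = np.random.default_rng(seed)
    init = _farthest_point_seeds(X, k, rng)
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300, random_state=0)
    return km.fit_predict(X).astype(np.int64)


def annotate_clusters(normalized: pd.DataFrame, clusters: np.ndarray,
                      markers: MarkerTable | None = None,
                      z_min: float = 1.0) -> CellAnnotation:
    """Label each cluster by its most elevated marker gene.

    Per cluster the mean normalized expression of each marker is z-scored
    across clusters. The cluster gets the type of the highest-z marker if
    that z >= ``z_min``; exclusive types (MPP) are assigned only when
    their marker alone clears ``z_min``; clusters with no elevated marker
    are ``Unknown``. Ties follow the marker table's declared type order.
    """
    markers = markers or MarkerTable()
    clusters = np.asarray(clusters)
    if clusters.shape[0] != normalized.shape[1]:
        raise DataError("cluster labels do not match the number of cells")
    for t, g in markers.markers.items():
        if g not in normalized.index:
            raise DataError(f"marker gene {g!r} (type {t}) not present in matrix")

    cluster_ids = np.unique(clusters)
    marker_expr = normalized.loc[list(markers.markers.values())]
    means = pd.DataFrame(
        {cid: marker_expr.iloc[:, clusters == cid].mean(axis=1) for cid in cluster_ids}
    ).T  # clusters x markers (marker gene names as columns)
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=0)
    z = (means - mu).div(sd.replace(0.0, np.inf), axis=1)

    non_exclusive = [t for t in markers.types if t not in markers.exclusive_types]
    labels = {}
    for cid in cluster_ids:
        zc = {t: z.loc[cid, markers.markers[t]] for t in markers.types}
        label = UNKNOWN
        for t in markers.exclusive_types:
            others_quiet = all(zc[o] < z_min for o in markers.types if o != t)
            if zc[t] >= z_min and others_quiet:
                label = t
                break
        if label == UNKNOWN:
            best = max(non_exclusive, key=lambda t: zc[t])
            # first-declared type wins exact ties
            for t in non_exclusive:
                if zc[t] == zc[best]:
                    best = t
                    break
            if zc[best] >= z_min:
                label = best
        labels[cid] = label

    cells = pd.DataFrame(
        {
            "cluster": clusters,
            "cell_type": [labels[c] for c in clusters],
        },
        index=pd.Index(normalized.columns, name="barcode"),
    )
    cluster_table = z.copy()
    cluster_table.columns = [f"z_{g}" for g in cluster_table.columns]
    cluster_table["cell_type"] = [labels[c] for c in cluster_ids]
    cluster_table.index.name = "cluster"
    return CellAnnotation(cells=cells, clusters=cluster_table)
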