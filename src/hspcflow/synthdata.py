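"""Synthetic UMI-matrix generator with planted, recoverable structure.

The generator emulates the statistical skeleton the downstream analysis
assumes: four experimental conditions (WT/Mut genotype x normal/fatty
bone marrow niche), eight HSPC cell types each carrying one enriched
marker gene, condition-specific inflammatory gene modules (IFN-alpha and
IFN-gamma response sets sharing 73 of the 98 IFN-alpha genes, an
IL-6/JAK/STAT3 set, a TNF-alpha set, and a signal-free control set),
log-normal library sizes, and QC contaminants (near-empty wells and
doublets). Counts are multinomial draws from per-cell expected
expression, so column totals equal the drawn library sizes exactly and
the null behaviour of every downstream statistic is known.

Ground truth (cell type, condition, library size, contaminant class per
barcode) is returned alongside the matrix for recovery testing.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .annotate import DEFAULT_MARKERS
from .errors import ConfigError
from .genesets import GeneSet, GeneSetCollection
from .matrix import UmiMatrix

log = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "ModuleSpec",
    "SimConfig",
    "SimTruth",
    "make_default_config",
    "make_gene_sets",
    "simulate_experiment",
    "spike_contaminants",
]

# Hallmark-style names for the simulated inflammatory modules.
IFNA = "HALLMARK_INTERFERON_ALPHA_RESPONSE"
IFNG = "HALLMARK_INTERFERON_GAMMA_RESPONSE"
IL6 = "HALLMARK_IL6_JAK_STAT3_SIGNALING"
TNFA = "HALLMARK_TNFA_SIGNALING_VIA_NFKB"
NULL_SET = "RANDOM_CONTROL"


@dataclass(frozen=True)
class Condition:
    label: str
    genotype: str  # WT | Mut
    niche: str     # NBM | FBM


@dataclass(frozen=True)
class ModuleSpec:
    """A named gene module of a given size (overlaps declared separately)."""

    name: str
    size: int


@dataclass
class SimConfig:
    """All knobs of the simulation; defaults are the study conditions.

    ``type_fractions`` maps condition label -> cell type -> fraction
    (summing to 1); ``module_fold`` maps condition label -> module name
    -> multiplicative fold applied to that module's genes in every cell
    of the condition; ``module_overlaps`` lists (set_a, set_b, n_shared).
    Library sizes are log-normal (natural-log parameters).
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 500
    conditions: list = field(default_factory=lambda: [
        Condition("NBM_WT", "WT", "NBM"),
        Condition("FBM_WT", "WT", "FBM"),
        Condition("NBM_Mut", "Mut", "NBM"),
        Condition("FBM_Mut", "Mut", "FBM"),
    ])
    type_fractions: dict = field(default_factory=dict)
    marker_fold: float = 20.0
    markers: dict = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    module_specs: list = field(default_factory=lambda: [
        ModuleSpec(IFNA, 98),
        ModuleSpec(IFNG, 200),
        ModuleSpec(IL6, 87),
        ModuleSpec(TNFA, 200),
        ModuleSpec(NULL_SET, 100),
    ])
    module_overlaps: list = field(default_factory=lambda: [(IFNA, IFNG, 73)])
    module_fold: dict = field(default_factory=lambda: {
        "FBM_Mut": {IL6: 2.0, IFNG: 1.5},
    })
    library_size_log_mean: float = math.log(3000.0)
    library_size_log_sd: float = 0.2
    frac_empty: float = 0.05
    frac_doublet: float = 0.03
    empty_umi_range: tuple = (50, 450)
    empty_mito_fold: float = 100.0
    mito_genes: int = 10
    baseline_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.type_fractions:
            self.type_fractions = _default_type_fractions(
                [c.label for c in self.conditions], list(self.markers)
            )
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_condition < 1:
            raise ConfigError("n_genes and n_cells_per_condition must be >= 1")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be unique")
        for c in self.conditions:
            if c.genotype not in ("WT", "Mut") or c.niche not in ("NBM", "FBM"):
                raise ConfigError(f"invalid genotype/niche in condition {c.label!r}")
        types = list(self.markers)
        for label in labels:
            if label not in self.type_fractions:
                raise ConfigError(f"type_fractions missing condition {label!r}")
            fr = self.type_fractions[label]
            if set(fr) != set(types):
                raise ConfigError(f"type_fractions[{label!r}] must cover all cell types")
            vals = np.array([fr[t] for t in types], dtype=float)
            if (vals < 0).any():
                raise ConfigError("cell-type fractions must be non-negative")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"type_fractions[{label!r}] sum to {vals.sum()!r}, not 1"
                )
        if self.marker_fold <= 1:
            raise ConfigError("marker_fold must exceed 1")
        sizes = {}
        for spec in self.module_specs:
            if spec.size < 1:
                raise ConfigError(f"module {spec.name!r} must have size >= 1")
            if spec.name in sizes:
                raise ConfigError(f"duplicate module name {spec.name!r}")
            sizes[spec.name] = spec.size
        shared = {name: 0 for name in sizes}
        for a, b, k in self.module_overlaps:
            if a not in sizes or b not in sizes:
                raise ConfigError(f"overlap refers to unknown module ({a!r}, {b!r})")
            if k < 0 or k > min(sizes[a], sizes[b]):
                raise ConfigError(
                    f"overlap {k} between {a!r} and {b!r} exceeds the smaller set"
                )
            shared[a] += k
            shared[b] += k
        for name, n_shared in shared.items():
            if n_shared > sizes[name]:
                raise ConfigError(f"overlaps of module {name!r} exceed its size")
        for label, folds in self.module_fold.items():
            if label not in labels:
                raise ConfigError(f"module_fold for unknown condition {label!r}")
            for name, f in folds.items():
                if name not in sizes:
                    raise ConfigError(f"module_fold for unknown module {name!r}")
                if f < 0:
                    raise ConfigError("module folds must be non-negative")
        if not (0 <= self.frac_empty < 1 and 0 <= self.frac_doublet < 1):
            raise ConfigError("contaminant fractions must be in [0, 1)")
        if self.library_size_log_sd < 0:
            raise ConfigError("library_size_log_sd must be non-negative")
        n_module_genes = sum(sizes.values()) - sum(k for _, _, k in self.module_overlaps)
        reserved = len(self.markers) + self.mito_genes + n_module_genes
        if reserved > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} cannot host {len(self.markers)} markers, "
                f"{self.mito_genes} mito genes and {n_module_genes} module genes"
            )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [asdict(c) for c in self.conditions]
        d["module_specs"] = [asdict(s) for s in self.module_specs]
        d["module_overlaps"] = [list(o) for o in self.module_overlaps]
        d["empty_umi_range"] = list(self.empty_umi_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = copy.deepcopy(d)
        d["conditions"] = [Condition(**c) for c in d.get("conditions", [])] or None
        if d["conditions"] is None:
            d.pop("conditions")
        if "module_specs" in d:
            d["module_specs"] = [ModuleSpec(**s) for s in d["module_specs"]]
        if "module_overlaps" in d:
            d["module_overlaps"] = [tuple(o) for o in d["module_overlaps"]]
        if "empty_umi_range" in d:
            d["empty_umi_range"] = tuple(d["empty_umi_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _default_type_fractions(labels, types) -> dict:
    """Elevated HSC pool in FBM_Mut (0.20), basal 0.02 elsewhere; the
    remainder split across progenitors with a myeloid-leaning profile."""
    basal = {
        "HSC": 0.02, "MLP": 0.10, "CMP": 0.24, "MegK": 0.10,
        "Ery": 0.15, "MonoP": 0.15, "DC": 0.09, "MPP": 0.15,
    }
    expanded = {
        "HSC": 0.20, "MLP": 0.08, "CMP": 0.20, "MegK": 0.08,
        "Ery": 0.12, "MonoP": 0.12, "DC": 0.08, "MPP": 0.12,
    }
    if set(types) != set(basal):
        # non-default marker tables get uniform fractions
        u = {t: 1.0 / len(types) for t in types}
        return {label: dict(u) for label in labels}
    return {
        label: dict(expanded if label == "FBM_Mut" else basal) for label in labels
    }


@dataclass
class SimTruth:
    """Ground truth per emitted barcode plus the realized config.

    ``cells`` is indexed by barcode with columns ``cell_type``,
    ``condition``, ``library_size`` and ``contaminant`` (none | empty |
    doublet).
    """

    cells: pd.DataFrame
    config: SimConfig

    def cell_type_of(self, barcode: str) -> str:
        return self.cells.loc[barcode, "cell_type"]

    def condition_of(self, barcode: str) -> str:
        return self.cells.loc[barcode, "condition"]

    def library_size_of(self, barcode: str) -> int:
        return int(self.cells.loc[barcode, "library_size"])

    def is_contaminant(self, barcode: str) -> str:
        return self.cells.loc[barcode, "contaminant"]


def make_default_config(**overrides) -> SimConfig:
    """The default simulation: 4 conditions, 8 cell types, a tenfold HSC
    expansion in FBM_Mut, IL-6 (x2.0) and IFN-gamma (x1.5) module
    activation in FBM_Mut, and the 98/73 IFN-alpha/IFN-gamma overlap."""
    return SimConfig(**overrides)


def gene_universe(cfg: SimConfig) -> np.ndarray:
    """Deterministic gene-name universe: markers, then mitochondrial
    genes (``mt-`` prefix), then numbered filler genes."""
    names = list(cfg.markers.values())
    names += [f"mt-Sim{i:03d}" for i in range(cfg.mito_genes)]
    n_filler = cfg.n_genes - len(names)
    names += [f"Gene{i:05d}" for i in range(n_filler)]
    return np.asarray(names, dtype=object)


def make_gene_sets(cfg: SimConfig, seed: int) -> GeneSetCollection:
    """Draw the module gene sets from the filler-gene universe.

    Sizes and pairwise overlaps follow ``cfg.module_specs`` /
    ``cfg.module_overlaps`` exactly; marker and mitochondrial genes are
    never module members. Deterministic given ``seed``.
    """
    cfg.validate()
    universe = gene_universe(cfg)
    filler = [g for g in universe if g.startswith("Gene")]
    rng = np.random.default_rng(seed)
    pool = list(rng.permutation(filler))

    members = {spec.name: [] for spec in cfg.module_specs}
    for a, b, k in cfg.module_overlaps:
        shared, pool = pool[:k], pool[k:]
        members[a].extend(shared)
        members[b].extend(shared)
    for spec in cfg.module_specs:
        n_exclusive = spec.size - len(members[spec.name])
        take, pool = pool[:n_exclusive], pool[n_exclusive:]
        members[spec.name].extend(take)

    collection = GeneSetCollection()
    for spec in cfg.module_specs:
        collection.add(GeneSet(name=spec.name, genes=tuple(members[spec.name]),
                               description="simulated module"))
    return collection


def _baseline_profile(cfg: SimConfig, genes: np.ndarray) -> np.ndarray:
    """Shared baseline expression: a symmetric Dirichlet draw fixed by
    ``cfg.seed``, with every marker gene pinned to the mean share
    (1/n_genes) so markers are reliably detectable before their fold is
    applied — mirroring the robust expression of real lineage markers."""
    rng = np.random.default_rng(cfg.seed)
    baseline = rng.dirichlet(np.full(cfg.n_genes, cfg.baseline_alpha))
    gi = {g: i for i, g in enumerate(genes)}
    marker_idx = [gi[m] for m in cfg.markers.values()]
    baseline[marker_idx] = 1.0 / cfg.n_genes
    return baseline / baseline.sum()


def _expected_profiles(cfg, genes, sets):
    """Per (condition, type) expected expression vectors and baseline."""
    baseline = _baseline_profile(cfg, genes)
    gi = {g: i for i, g in enumerate(genes)}
    profiles = {}
    for cond in cfg.conditions:
        cond_mult = np.ones(cfg.n_genes)
        for set_name, fold in cfg.module_fold.get(cond.label, {}).items():
            idx = [gi[g] for g in sets[set_name].genes]
            cond_mult[idx] *= fold
        for cell_type, marker in cfg.markers.items():
            p = baseline * cond_mult
            p[gi[marker]] *= cfg.marker_fold
            profiles[(cond.label, cell_type)] = p / p.sum()
    return baseline, profiles, gi


def simulate_experiment(cfg: SimConfig) -> tuple:
    """Simulate the full experiment: real cells plus contaminants.

    For each condition, cell types are drawn from ``type_fractions``,
    library sizes from the log-normal, and counts from a multinomial over
    the condition/type expected profile (baseline x marker fold x module
    folds). Contaminants are appended by :func:`spike_contaminants`.
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    genes = gene_universe(cfg)
    sets = make_gene_sets(cfg, cfg.seed)
    baseline, profiles, gi = _expected_profiles(cfg, genes, sets)

    rng = np.random.default_rng(cfg.seed + 1)
    types = list(cfg.markers)
    columns, barcodes, records = [], [], []
    for cond in cfg.conditions:
        fr = np.array([cfg.type_fractions[cond.label][t] for t in types])
        n = cfg.n_cells_per_condition
        drawn_types = rng.choice(types, size=n, p=fr / fr.sum())
        libs = rng.lognormal(cfg.library_size_log_mean,
                             cfg.library_size_log_sd, size=n)
        libs = np.maximum(1, np.round(libs)).astype(np.int64)
        for i in range(n):
            columns.append(rng.multinomial(libs[i], profiles[(cond.label, drawn_types[i])]))
            barcodes.append(f"{cond.label}_{i:05d}")
            records.append({
                "barcode": barcodes[-1], "cell_type": drawn_types[i],
                "condition": cond.label, "genotype": cond.genotype,
                "niche": cond.niche, "library_size": int(libs[i]),
                "contaminant": "none",
            })

    counts = np.asarray(columns, dtype=np.int64).T  # genes x cells
    cells = pd.DataFrame(records).set_index("barcode")
    matrix = UmiMatrix(
        counts=counts, genes=genes, barcodes=np.asarray(barcodes, dtype=object),
        cell_meta=cells[["condition", "genotype", "niche"]],
    )
    truth = SimTruth(cells=cells, config=copy.deepcopy(cfg))
    return spike_contaminants(matrix, truth, cfg, rng=rng)


def spike_contaminants(matrix: UmiMatrix, truth: SimTruth, cfg: SimConfig,
                       rng: np.random.Generator | None = None) -> tuple:
    """Append empty-well cells and doublets to a simulated matrix.

    Empty cells have uniform totals in ``cfg.empty_umi_range`` (at or
    below the QC floor) drawn from the baseline profile with mitochondrial
    genes boosted ``cfg.empty_mito_fold``-fold, emulating ambient RNA from
    damaged cells. Doublets are sums of two distinct real cells of the
    same condition, landing in the upper library-size tail.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n_real = matrix.n_cells
    n_empty = int(round(cfg.frac_empty * n_real))
    n_doublet = int(round(cfg.frac_doublet * n_real))
    if n_empty == 0 and n_doublet == 0:
        return matrix, truth

    genes = matrix.genes
    baseline = _baseline_profile(cfg, genes)
    mito_idx = np.array([i for i, g in enumerate(genes) if g.startswith("mt-")],
                        dtype=np.int64)
    empty_profile = baseline.copy()
    if mito_idx.size:
        empty_profile[mito_idx] *= cfg.empty_mito_fold
    empty_profile /= empty_profile.sum()

    cond_labels = truth.cells.loc[list(matrix.barcodes), "condition"].to_numpy()
    dense = matrix.dense()
    new_cols, new_records = [], []
    lo, hi = cfg.empty_umi_range
    for i in range(n_empty):
        total = int(rng.integers(lo, hi + 1))
        new_cols.append(rng.multinomial(total, empty_profile))
        cond = cfg.conditions[int(rng.integers(len(cfg.conditions)))]
        new_records.append({
            "barcode": f"empty_{i:05d}", "cell_type": UNKNOWN_TYPE,
            "condition": cond.label, "genotype": cond.genotype,
            "niche": cond.niche, "library_size": total, "contaminant": "empty",
        })
    for i in range(n_doublet):
        a = int(rng.integers(n_real))
        same_cond = np.flatnonzero(cond_labels == cond_labels[a])
        b = a
        while b == a:
            b = int(same_cond[rng.integers(same_cond.size)])
        col = dense[:, a] + dense[:, b]
        new_cols.append(col)
        ra = truth.cells.loc[matrix.barcodes[a]]
        new_records.append({
            "barcode": f"doublet_{i:05d}", "cell_type": ra["cell_type"],
            "condition": ra["condition"], "genotype": ra["genotype"],
            "niche": ra["niche"], "library_size": int(col.sum()),
            "contaminant": "doublet",
        })

    spiked = np.concatenate([dense, np.asarray(new_cols, dtype=np.int64).T], axis=1)
    new_cells = pd.DataFrame(new_records).set_index("barcode")
    all_cells = pd.concat([truth.cells, new_cells])
    all_barcodes = np.concatenate([matrix.barcodes, new_cells.index.to_numpy()])
    out = UmiMatrix(
        counts=spiked, genes=genes, barcodes=all_barcodes,
        cell_meta=all_cells[["condition", "genotype", "niche"]],
    )
    return out, SimTruth(cells=all_cells, config=truth.config)


#: truth label for cells with no biological identity (empty wells)
UNKNOWN_TYPE = "none"
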