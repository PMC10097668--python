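"""End-to-end pipeline driver: QC -> annotate -> composition;
QC -> downsample -> score -> compare; DE ranking -> preranked GSEA.

All stage outputs are returned in a result bundle and, when an output
directory is given, written as TSVs next to a JSON manifest recording
package version, parameters, seeds, and per-stage cell counts, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (MarkerTable, annotate_clusters, cluster_cells,
                       normalize_log, select_variable_genes)
from .composition import compare_abundances, composition_table
from .enrichment import gsea_preranked, rank_by_fold_change
from .errors import ConfigError
from .genesets import read_gmt
from .io import read_counts_dir, write_counts_dir, write_manifest
from .matrix import UmiMatrix
from .qc import QcParams, filter_cells
from .signatures import (DEFAULT_DEPTH, compare_scores, comparison_frame,
                         downsample, score_cells)
from .synthdata import SimConfig, make_gene_sets, simulate_experiment

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of the full analysis run.

    Exactly one of ``in_dir`` (a counts directory with a cells.tsv
    carrying the condition column) or ``sim`` (a simulation config) must
    be provided. ``gmt`` supplies the gene sets; when absent and the
    input is simulated, the simulation's own module sets are used.
    """

    in_dir: str | None = None
    out_dir: str | None = None
    sim: SimConfig | None = None
    gmt: str | None = None
    qc: QcParams = field(default_factory=QcParams)
    k: int = 32
    z_min: float = 1.0
    n_top_genes: int = 30
    exclude_genes: tuple = ()
    focal_type: str = "HSC"
    focal_condition: str = "FBM_Mut"
    depth: int = DEFAULT_DEPTH
    n_perm: int = 1000
    exponent: float = 1.0
    pseudocount: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if (self.in_dir is None) == (self.sim is None):
            raise ConfigError("provide exactly one of in_dir or sim")
        if self.in_dir is not None and not Path(self.in_dir).exists():
            raise ConfigError(f"input directory {self.in_dir!r} does not exist")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise ConfigError(f"GMT file {self.gmt!r} does not exist")
        if self.gmt is None and self.sim is None:
            raise ConfigError("a GMT file is required for non-simulated input")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = QcParams(**raw["qc"])
        if "exclude_genes" in raw:
            raw["exclude_genes"] = tuple(raw["exclude_genes"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the result bundle.

    Bundle keys: matrix (QC-filtered), qc_report, annotation,
    composition, abundance (list of AbundanceResult), scores,
    score_comparisons, ranked, gsea, truth (simulated input only),
    manifest.
    """
    config.validate()
    seed = config.seed
    truth = None
    if config.sim is not None:
        matrix, truth = simulate_experiment(config.sim)
        sets = make_gene_sets(config.sim, config.sim.seed)
    else:
        matrix = read_counts_dir(config.in_dir)
        sets = None
    if config.gmt is not None:
        sets = read_gmt(config.gmt)
    if "condition" not in matrix.cell_meta.columns:
        raise ConfigError("input cells lack a 'condition' metadata column")
    n_input = matrix.n_cells

    # --- QC ------------------------------------------------------------
    matrix, qc_report = filter_cells(matrix, config.qc)
    log.info("QC kept %d of %d cells (low=%d, top=%d, mito=%d)",
             qc_report.n_kept, qc_report.n_input, qc_report.n_removed_low,
             qc_report.n_removed_top, qc_report.n_removed_mito)

    # --- annotation ----------------------------------------------------
    normalized = normalize_log(matrix)
    variable = select_variable_genes(normalized, config.n_top_genes,
                                     exclude=config.exclude_genes)
    clusters = cluster_cells(normalized, variable, k=config.k, seed=seed)
    annotation = annotate_clusters(normalized, clusters,
                                   markers=MarkerTable(), z_min=config.z_min)

    # --- composition ---------------------------------------------------
    table = composition_table(annotation, matrix.cell_meta)
    conditions = list(table.counts.columns)
    pairs = [(config.focal_condition, c) for c in conditions
             if c != config.focal_condition]
    abundance = compare_abundances(table, config.focal_type, pairs)

    # --- signature scores ----------------------------------------------
    ds = downsample(matrix, depth=config.depth, seed=seed + 1)
    scores = score_cells(ds, sets, depth=config.depth)
    score_comparisons = compare_scores(scores, focal=config.focal_condition)

    # --- DE ranking + GSEA ----------------------------------------------
    in_group = matrix.cell_meta["condition"].to_numpy() == config.focal_condition
    ranked = rank_by_fold_change(ds, in_group, pseudocount=config.pseudocount)
    gsea = gsea_preranked(ranked, sets, n_perm=config.n_perm, seed=seed + 2,
                          exponent=config.exponent)

    manifest = {
        "package": "hspcflow",
        "version": __version__,
        "seed": seed,
        "parameters": {
            "qc": asdict(config.qc),
            "k": config.k, "z_min": config.z_min,
            "n_top_genes": config.n_top_genes,
            "depth": config.depth, "n_perm": config.n_perm,
            "exponent": config.exponent, "pseudocount": config.pseudocount,
            "focal_type": config.focal_type,
            "focal_condition": config.focal_condition,
            "matrix_orientation": "genes x cells",
        },
        "stages": {
            "input_cells": n_input,
            "qc_kept": qc_report.n_kept,
            "qc_removed_low": qc_report.n_removed_low,
            "qc_removed_top": qc_report.n_removed_top,
            "qc_removed_mito": qc_report.n_removed_mito,
            "clusters": int(config.k),
            "scored_cells": int((~scores.below_depth).sum()),
        },
    }

    bundle = {
        "matrix": matrix, "qc_report": qc_report, "annotation": annotation,
        "composition": table, "abundance": abundance, "scores": scores,
        "score_comparisons": score_comparisons, "ranked": ranked,
        "gsea": gsea, "truth": truth, "manifest": manifest,
    }
    if config.out_dir is not None:
        _write_outputs(bundle, config)
    return bundle


def _write_outputs(bundle, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["qc_report"].disposition.to_csv(out / "qc_disposition.tsv", sep="\t")
    ann = bundle["annotation"]
    cells = ann.cells.join(bundle["matrix"].cell_meta)
    cells.to_csv(out / "annotation.tsv", sep="\t")
    ann.clusters.to_csv(out / "clusters.tsv", sep="\t")
    bundle["composition"].counts.to_csv(out / "composition.tsv", sep="\t")
    pd.DataFrame([{**{k: v for k, v in r.__dict__.items() if k != "table"}}
                  for r in bundle["abundance"]]).to_csv(
        out / "abundance.tsv", sep="\t", index=False)
    bundle["scores"].scores.to_csv(out / "scores.tsv", sep="\t")
    comparison_frame(bundle["score_comparisons"]).to_csv(
        out / "score_comparisons.tsv", sep="\t", index=False)
    ranked = bundle["ranked"]
    pd.DataFrame({"gene": ranked.genes, "metric": ranked.metric}).to_csv(
        out / "ranked_genes.tsv", sep="\t", index=False)
    bundle["gsea"].to_csv(out / "gsea.tsv", sep="\t")
    write_manifest(out / "manifest.json", bundle["manifest"])
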