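# hspcflow

Single-cell UMI analysis of hematopoietic stem/progenitor (HSPC)
composition and inflammatory gene-set activation.

## The problem

Clonal hematopoiesis mutations such as those in *DNMT3A* give blood
stem cells a context-dependent fitness advantage. One context of
interest is an adipocyte-rich ("fatty") bone-marrow niche: when
mutant HSPCs are exposed to fatty marrow (FBM) rather than normal
marrow (NBM), do they preserve their hematopoietic stem cell (HSC)
pool, and do they switch on inflammatory signalling (IL-6, IFN-γ)?
Answering this from single-cell RNA-seq requires a chain of careful,
individually testable steps, which this package implements as a
reusable library plus CLI:

1. **QC** — keep cells with more than 450 UMIs, drop cells in the top
   3% of UMI totals (doublets) and cells with a high mitochondrial
   fraction;
2. **annotation** — partition cells into k = 32 clusters (a
   deterministic centroid-based stand-in for metacell construction) and
   label each cluster by canonical markers: HSC *Procr*, MLP *Dntt*,
   CMP *Mpo*, MegK *Pf4*, Ery *Hba-a2*, MonoP *Irf8*, DC *Cd74*, and
   MPP by *Fgd5* with no other marker elevated;
3. **composition** — cross-tabulate cell type × condition and test HSC
   abundance differences with a two-sided Fisher exact test
   (point-probability rule) and BH correction;
4. **signature scores** — downsample every cell to a fixed depth of
   750 UMIs (vector hypergeometric, exact totals) and score each gene
   set as the plain sum of downsampled counts, comparing conditions
   with Wilcoxon rank-sum tests under one BH family; set algebra
   (e.g. the IFN-α set minus its 73 genes shared with IFN-γ) isolates
   pathway-specific signal;
5. **enrichment** — rank genes by median-centered log2 fold change of
   the focal group versus the rest and run preranked GSEA from scratch:
   weighted Kolmogorov–Smirnov running-sum ES, gene-permutation null,
   NES, permutation p and BH q, with sets flagged at q < 0.2.

Because the original deposited datasets are not needed to verify the
*method*, the package ships a first-class synthetic data generator
(`hspcflow.synthdata`) that emulates the assumed statistical structure —
four conditions (WT/Mut × NBM/FBM), eight marker-defined cell types,
log-normal library sizes, planted HSC expansion and inflammatory module
folds, empty wells and doublets — together with per-barcode ground
truth, so every stage is tested by parameter recovery.

## Worked example

```python
from hspcflow import PipelineConfig, SimConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(sim=SimConfig(n_cells_per_condition=1000,
                                                   seed=1), seed=1))

hsc = next(r for r in bundle["abundance"] if r.cond_b == "FBM_WT")
print(f"HSC fold (Mut-FBM vs WT-FBM): {hsc.fold:.2f}  Fisher p = {hsc.p:.2e}")
print(bundle["gsea"][["nes", "q", "significant"]])
```

prints

```
HSC fold (Mut-FBM vs WT-FBM): 9.87  Fisher p = 3.74e-44
                                         nes         q  significant
set
HALLMARK_INTERFERON_ALPHA_RESPONSE  1.871730  0.001668         True
HALLMARK_INTERFERON_GAMMA_RESPONSE  2.124179  0.001668         True
HALLMARK_IL6_JAK_STAT3_SIGNALING    2.081377  0.001668         True
HALLMARK_TNFA_SIGNALING_VIA_NFKB   -0.422502  1.000000        False
RANDOM_CONTROL                     -0.700166  1.000000        False
```

The simulation planted a 0.20 vs 0.02 HSC fraction (tenfold) in Mut-FBM
and activated only the IL-6 (×2.0) and IFN-γ (×1.5) modules there; the
pipeline recovers the tenfold HSC enrichment at a vanishing Fisher p
and flags exactly the activated sets (IFN-α is carried by its 73 genes
shared with IFN-γ, the motivation for the exclusive-set reanalysis in
`signatures.exclusive_sets`), while the TNF-α and random control sets
stay unflagged.

The same pipeline runs from the shell:

```bash
hspcflow simulate --seed 1 --out sim/
hspcflow run-all --seed 1 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `hspcflow.synthdata` | `SimConfig`, `simulate_experiment`, `make_gene_sets`, contaminant spiking, ground truth |
| `hspcflow.qc` | `QcParams`, `filter_cells`, `cell_totals`, per-cell disposition report |
| `hspcflow.annotate` | normalization, variable genes, seeded k-means, marker z-score labelling |
| `hspcflow.composition` | composition tables, `fisher_exact_2x2`, abundance fold/p/q |
| `hspcflow.signatures` | `downsample`, sum scores, `exclusive_sets`, `wilcoxon_rank_sum`, `bh_adjust` |
| `hspcflow.enrichment` | fold-change ranking, `enrichment_score`, `gsea_preranked` |
| `hspcflow.io` / `hspcflow.pipeline` / `hspcflow.cli` | MTX/GMT/TSV I/O, `run_pipeline`, CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
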