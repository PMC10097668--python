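# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical conventions.

## Synthetic data model

Counts for a cell of type *t* in condition *c* are drawn as

> n ~ LogNormal(log 3000, 0.2) rounded to an integer,
> counts ~ Multinomial(n, p<sub>c,t</sub>)

where the expected expression p<sub>c,t</sub> is a shared baseline
profile multiplied by `marker_fold` (default 20) on type *t*'s marker
gene and by `module_fold[c][S]` on every gene of module *S*, then
renormalized. The multinomial has no extra overdispersion: under this
model the null behaviour of every downstream statistic (Fisher,
rank-sum, permutation GSEA) is known exactly, which is the property the
recovery tests rely on. Overdispersion can be layered on via the config
but is deliberately not the default.

Choices that matter:

- **Baseline profile** — one symmetric Dirichlet(α = 1) draw shared by
  all types and conditions, fixed by the seed. Marker genes are pinned
  to the mean share (1/n_genes) before their fold is applied: real
  lineage markers (*Procr*, *Pf4*, …) are robustly expressed in their
  lineage, and an unpinned Dirichlet draw occasionally hands a marker a
  negligible baseline, making the type undetectable by construction
  rather than by biology.
- **Library sizes** — log-normal, median 3000 UMIs, log-sd 0.2
  (CV ≈ 20 %, the within-batch spread of plate-sorted MARS-seq-scale
  data). The median sits between the two regimes the workflow must
  serve (a 450-UMI QC floor on the low end, ~9400-UMI 10X libraries on
  the high end; both reachable via config). The narrow spread is also
  what makes a fixed 3 % upper-percentile cut a meaningful doublet
  filter: doublet totals (sums of two cells) must be separable from the
  singlet upper tail.
- **Conditions and planted effects (the study conditions)** — four
  conditions (WT/Mut × NBM/FBM); HSC fraction 0.20 in Mut-FBM versus
  0.02 elsewhere (a tenfold expansion); IL-6 module ×2.0 and IFN-γ
  module ×1.5 in Mut-FBM only. Module sizes follow the Hallmark
  collection: IFN-α 98 genes sharing 73 with the 200-gene IFN-γ set,
  IL-6/JAK/STAT3 87, TNF-α 200, plus a 100-gene signal-free control
  set. 500 cells/condition by default (~2000 analyzed cells, the
  MARS-seq scale of the motivating experiment); recovery tests use
  1000.
- **Contaminants** — 5 % empty wells (uniform 50–450 total UMIs, drawn
  from the baseline with mitochondrial genes boosted ×100, emulating
  ambient RNA from damaged cells) and 3 % doublets (sums of two random
  real cells of the same condition). Ground truth records the class of
  every barcode.

What the generator does **not** emulate: plate/batch structure, UMI
collision noise, ERCC spike-ins, overdispersed (e.g. NB) counts,
cell-cycle/stress programs, multi-gene cell-type programs (each type is
defined by a single marker), or doublets across conditions. Passing
recovery tests therefore demonstrate correctness of the *computational
chain* under the assumed sampling model, not robustness to every
property of real data.

## QC

Cells are kept when total UMIs strictly exceed `min_umi` (450). Among
survivors, cells strictly above the (100 − `top_pct`) linear-
interpolation percentile of survivor totals are removed (`top_pct` = 3).
The percentile is computed *after* the floor so that empty wells cannot
drag the cutoff down; each removed cell gets exactly one reason with
fixed priority floor → percentile → mito, making the report counts
well-defined. The mitochondrial threshold (fraction > 0.20, `mt-`
prefix or explicit list) is a conventional default; the motivating
analysis states only that high-mito cells were excluded. Re-applying
the filter can remove up to `top_pct` of cells again (the percentile is
relative); the pipeline applies it exactly once.

## Annotation

Log-normalized expression (10 000 UMIs per cell, log1p) of the
`n_top_genes` most variable genes (default 30) is clustered with
Lloyd's algorithm from greedy farthest-point seeds, k = 32 by default.
This replaces graph-based metacell partitioning — an external published
algorithm that is out of scope — with a deterministic, seeded stand-in;
the biology is carried by the labelling rule, not the partitioner. The
small default gene panel matches the simulation, where type identity
lives in eight marker genes; on real data users should widen it (and
may pass an exclusion list for cell-cycle/stress genes).

Each cluster's mean expression of each marker is z-scored **across
clusters**; a cluster takes the type of its highest-z marker when that
z ≥ `z_min` (default 1.0, our concretization of "annotated by known
genes"), and is otherwise Unknown. MPP is exclusive: granted only when
*Fgd5* is elevated and no other marker is; if another marker is also
elevated, *Fgd5* is ignored and the best remaining marker wins. Ties
follow the declared marker order. Limitation: a marker that is flat in
every cluster still gets unit-scale z-scores (standardized noise), so
labels for types absent from the data can be spurious — the Unknown
margin and the cluster z table in the output exist to catch this.

## Composition testing

Cell type × condition counts, with Unknown cells excluded from the
"all other" pool by default. Each comparison collapses to a 2×2 table
(focal type vs rest × condition A vs B). The two-sided Fisher p sums
hypergeometric probabilities of all tables with the observed margins
whose point probability is ≤ that of the observed table; a relative
1 + 1e−12 slack absorbs floating-point ties (an absolute slack would
misbehave when the observed probability is far below 1e−12). Fold
change is the ratio of focal fractions, with a Haldane +0.5 per cell
only when a zero cell occurs. BH adjustment runs across the requested
batch of comparisons.

## Signature scores

The whole matrix is downsampled to `depth` = 750 UMIs per cell by a
multivariate hypergeometric draw (a uniform subset of the cell's actual
UMIs — totals are exact, unlike multinomial thinning). Cells at or
below depth are kept unchanged, flagged, and excluded from group tests
by default: their sums live on a different scale. A cell's score for a
set is the plain sum of downsampled counts over the set's genes; genes
absent from the matrix contribute zero (logged once per set).

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration (subset-sum DP over rank distributions) when both groups
have ≤ 8 observations without ties, otherwise the normal approximation
with tie and continuity corrections, floored at 1e−300 so p stays in
(0, 1]. One BH family spans the entire invocation batch (all sets × all
pairs); the family definition is a convention and is documented rather
than configurable. The "95 % confidence interval" sometimes attached to
rank-sum results in figure legends is ambiguous and not implemented;
only p and q are reported.

## Preranked GSEA

Genes are ranked by log2((mean_in + α)/(mean_out + α)) with α = 0.1 on
the downsampled matrix, focal group versus the rest. The metric is
**median-centered** by default: depth-matched counts are compositional,
so genuinely upregulated modules push every unchanged gene slightly
negative, and whole signal-free sets otherwise drift coherently to the
bottom of the ranking and acquire spurious negative enrichment.
Median-of-ratios centering (the same logic as DESeq size factors)
restores unchanged genes to zero; `center="none"` gives the raw ratio.

The ES is the classic weighted-KS running sum (hits weight
|metric|^p / Σ|metric|^p with p = 1 by default, misses 1/(N − |S|);
signed maximal deviation). The null is gene-label permutation — random
same-size gene draws, the only null available to a preranked input —
with NES = ES / mean(|null ES| of the same sign), one-tailed-within-sign
permutation p ≥ 1/(n_perm + 1), and BH q across sets (simpler and
better calibrated than the original split-null FDR; a deliberate,
documented deviation from the reference desktop implementation). Sets
with fewer than 5 genes in the ranking are skipped with a warning;
significance is q < 0.2, the conventional preranked threshold.

## Numerical and interface conventions

- Matrices are genes × cells everywhere, including on disk (Matrix
  Market coordinate integer, 1-based, plus genes/barcodes/cells TSVs).
- All randomness flows through named integer seeds (numpy Generator);
  no global RNG state. Reruns are byte-identical.
- Variable-gene ties break lexicographically; marker-z ties break by
  declared marker order; ranking ties break by gene name — every sort
  is total, so outputs are order-independent.
- Degenerate inputs raise typed errors rather than producing empty
  files: all-cells-removed QC, zero-total cells at normalization,
  empty exclusive sets, sets covering the whole ranking, groups below
  3 cells in comparisons.
- Problem sizes used by the test-suite recovery checks: 1000 cells per
  condition (composition/score/GSEA recovery), 300 (exclusive-set
  property), 500 (annotation accuracy), 10 seeds each — sizes at which
  the planted effects are comfortably detectable under the model above.

## Known limitations

The clustering stand-in is not a metacell algorithm and the default
30-gene panel is tailored to single-marker simulations; annotation
accuracy claims are with respect to the generator's model. The sum
score inherits compositional coupling between planted modules and all
other genes (mitigated in GSEA by median centering, not in the raw
scores). Exact rank-sum enumeration covers only small tie-free groups,
as specified; everything larger uses the corrected normal
approximation.
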