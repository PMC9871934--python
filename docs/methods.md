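# Methods

## The problem and the model

Aortic aneurysm single-cell studies profile the vessel wall in humans
(thoracic and abdominal disease vs adjacent normal tissue) and in the mouse
angiotensin-II infusion model.  The analytical core of such a comparison is
a *cell-type homology map*: a statement that, say, the human TREM2-type
macrophage and a particular mouse macrophage cluster are the same biological
entity.  `orthocell` operationalises that map as (i) a shared gene panel —
for each cell type present in both species, the intersection of the top-50
most enriched genes per side, translated through a strict one-to-one
ortholog table — and (ii) an argmax pairing of pseudobulk profiles over
that panel, with a dendrogram of all clusters of both species as the
supporting structure.

## Pipeline stages and their parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| gene filter | min cells per gene | 3 | drops undetectable genes |
| cell filter | detected genes per cell | [100, 4000] | excludes empty droplets and aggregates; closed interval (a literal reading of "fewer than 100 or greater than 4,000 … excluded") |
| cell filter | mitochondrial % | ≤ 5.0 | dying-cell exclusion; mito genes found by symbol prefix `MT-`/`mt-` (configurable; no fixed gene list is assumed) |
| doublets | expected rate | 0.05 | flags exactly `round(rate·n)` top-scoring barcodes |
| doublets | artificial doublet fraction | 0.25 | proportion of simulated barcode collisions mixed into the embedding |
| normalisation | scale factor | 10⁴ | counts-per-10k, natural log1p |
| HVG | n genes / bins | 2000 / 20 | binned standardised dispersion (z of log(var/mean) within equal-frequency mean bins), lexicographic tie-break |
| scaling | clip | ±10 | caps outlier cells' leverage |
| PCA | components | 30 | exact full-SVD solver; deterministic up to the fixed sign convention |
| clustering | k / resolution | 20 / 0.5 | Jaccard-weighted union-kNN graph; Leiden RB-configuration modularity, labels relabelled by decreasing size |
| markers | min_pct / only_pos | 0.1 / true | genes tested must be expressed in ≥10% of the cluster; BH within cluster |
| correspondence | top-n | 50 | per-type marker intersection depth |

### Doublet filter

DoubletFinder's idea in its simplest deterministic form: simulate
`0.25·n` artificial doublets by *pooling raw counts* of random cell pairs
and normalising the pooled barcode like any real one, embed real +
artificial profiles together (HVG subset, 30 PCs), and score each real cell
by the fraction of artificial profiles among its k = 20 nearest neighbours.
Pooling counts (rather than averaging normalised profiles) matters: real
doublets are count sums, and their characteristic geometry — a mixed
profile with the reduced sparsity of a double-depth barcode — is exactly
what the artificial population must reproduce for the kNN vote to find
them.  On generator data with 8% planted doublets the score's AUROC against
truth is ≈ 1.0; the flag keeps the top `round(expected_rate·n)` barcodes by
score, so the flagged count is exact by construction.

### Wilcoxon rank-sum

The scalar test delegates to scipy: exact permutation enumeration when
`n_x·n_y ≤ 400` and the pooled sample is tie-free, otherwise the normal
approximation with midranks, tie-corrected variance and a 0.5 continuity
correction.  Marker scans need thousands of such tests per cluster, so the
matrix path re-implements the asymptotic formula vectorised over genes and
— because every one-vs-rest test pools the *same* cells — computes each
gene's ranking once and reuses it for all clusters.  The vectorised path is
tested to agree with scipy's asymptotic mode to 1e-12, and the exact path
with full enumeration to 1e-12; the null type-I error at α = 0.05 over
2,000 NB simulations (n = 30 per side) stays within [0.03, 0.07].

### Fold change and dot-plot statistics

`avg_log2FC = log₂((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1))` — the
expm1-of-log-mean convention with +1 pseudocount common in scRNA-seq
toolkits, documented here because published methods sections rarely define
it.  Dot-plot summaries report, per (cluster, gene), the fraction of the
cluster's cells above the gene's grand mean, the cluster mean, and the
column-wise z-score of cluster means.

### Correspondence details

Pseudobulk = mean log-normalised expression per cluster.  Gene columns of
the stacked (species A + species B) pseudobulk matrix are z-scored across
the combined clusters — scaling across the union rather than within
species, so that a program high in both species stays comparable; this is a
deliberate choice where either convention is defensible, and it is
configurable by scaling before calling `correspondence`.  Distance is
`1 − Pearson` with average linkage: the standard metric for expression
profile trees and robust to the prior z-scoring.  The pairing is the
per-A-cluster argmax of Pearson similarity to B clusters rather than a tree
cut: argmax is deterministic, testable, and matches the way homology claims
are phrased ("every major cell type clustered with its homolog"); the
dendrogram (Newick + merge table) is still emitted for inspection.
Species-specific clusters are never suppressed — they appear in the pairing
with their best match and a visibly lower correlation.

### Gene-set scores and enrichment

Two module-score flavours: the plain per-cell mean of the set's
log-normalised values (the convention for T-cell immune-state calls from
resident/exhausted/cytotoxic/co-stimulatory panels — the bundled
`tcell_states.gmt` is an editable convenience compilation, not a claim of
reproducing any published supplementary list), and a control-adjusted score
subtracting the mean of `n_ctrl = 100` control genes per set gene, sampled
from the same average-expression bin (24 equal-frequency bins, seeded).  On
null data the control-adjusted score is centred at 0 (|mean| ≤ 0.05 at 500
cells).  Enrichment is the upper-tail hypergeometric test
`P(X ≥ overlap)` over a user-supplied GMT against a universe defaulting to
all post-QC genes, BH-corrected across the collection's sets; it matches
exact rational combinatorics on every configuration with universe ≤ 25.

## The synthetic generator

The generator emulates the *statistical structure* the analysis assumes:
two species sharing `n_celltypes = 5` orthologous cell-type programs (named
SMC, EC, Fibroblast, Macrophage, TCell) plus one private type per species;
NB counts with `Var = μ + μ²/θ`, baseline mean 2.0 per gene (≈ 2,200 UMI
per cell over the default ~1,100 genes — a desk-scale stand-in for real
droplet depth), dispersion θ = 1; 25 marker genes per type elevated 4-fold,
occupying the *same ortholog slots* in both species for shared programs;
13 mitochondrial genes carrying 3% of counts in expectation (per type, so
the target holds despite marker-driven depth differences); two conditions
(control/aneurysm) with composition multipliers ×0.4 for SMC and ×2.0 for
Macrophage and TCell in disease; and 5% doublets formed by summing the raw
counts of two uniformly drawn cells, replacing randomly chosen barcode
slots so the flagged fraction is exactly `round(rate·n)`.  Ortholog
identifiers follow the human/mouse symbol convention (`GENE7` ↔ `gene7`),
exercising ortholog-map parsing.  A single integer seed drives everything;
reruns are bit-identical.

### What the generator does *not* emulate

No ambient RNA, UMI saturation, batch-specific library-size distributions,
cell-cycle programs, or — importantly — *heterogeneous baseline gene
means*: all non-marker genes share one mean.  Two consequences for
interpreting green tests.  First, there are no batch effects, so the
gene-intersection merge used for multi-sample harmonisation (in place of
anchor-based integration, an external published algorithm deliberately not
re-implemented) is exercised only for bookkeeping, not for batch
correction; the correspondence step operates on pseudobulks, which are
robust to this substitution.  Second, binned-dispersion HVG selection
cannot *discriminate* markers on generator data when the selection size is
small: markers occupy the top mean-bins wholesale and the within-bin
z-scores cancel.  HVG discrimination is therefore tested on a dedicated
fixture with gamma-distributed baseline means (the regime the binned
statistic is designed for, and what real data look like), while pipeline
runs on generator data use a selection size that covers the gene panel.

## Problem sizes and determinism

Validation runs use 5 + 1 cell types × 200 cells (two conditions of 100)
and ~1,100 genes per species; the ground-truth evaluation
(`orthocell.evaluate.recover_cross_species`) repeats the full chain over
ten seeds and recovers all five planted homolog pairs in 10/10 seeds with
clustering ARI ≥ 0.95 against truth.  Cluster-to-type naming in that
evaluation uses majority planted label per cluster — the stand-in for the
manual marker-based annotation a real study performs; the package also
provides marker-YAML annotation (`annotate_clusters`) for real gene
symbols.  All stochastic steps (generation, doublet simulation, PCA solver,
Leiden, t-SNE, control-gene draws) take explicit seeds; the pipeline
derives per-stage seeds as `seed + stage_index` and writes them to the run
manifest.

## Known limitations

- Community detection on kNN graphs can split large homogeneous point
  clouds in low dimension (within-blob spatial modularity) — at the default
  resolution 0.5 this is visible for 2-D toy blobs with small k, and is a
  property of modularity clustering, not a defect of the implementation.
- The exact Wilcoxon path refuses nothing but does fall back to the
  asymptotic formula whenever ties are present, even for tiny samples.
- The 1:1 ortholog policy drops every gene involved in many-to-many
  homology; paralog-rich families therefore cannot contribute to the
  shared panel.
- QC thresholds are applied per sample (each sample directory is filtered
  independently before merging); whether a given published analysis
  filtered per sample or on the merged matrix is usually unstated, so this
  is a documented convention here, not a claim about any particular study.
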