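# orthocell

Cross-species cell-type homology mapping from single-cell RNA-seq.

Comparative studies of human disease and mouse models — here, thoracic and
abdominal aortic aneurysm versus the angiotensin-II infusion model — need a
principled answer to the question *which mouse cell type corresponds to
which human cell type?*  `orthocell` implements the full analysis chain as a
tested, reusable Python library:

- **QC**: genes detected in ≥ 3 cells; cells with 100–4,000 detected genes
  and ≤ 5% mitochondrial counts; a simplified doublet filter that scores
  each barcode by its k-nearest-neighbour vote against simulated artificial
  doublets.
- **Preprocessing**: log normalisation `ln(1 + c·10⁴/library)`, top-2,000
  highly variable genes by binned standardised dispersion, per-gene scaling,
  30-component PCA.
- **Clustering**: Jaccard-weighted kNN graph, Leiden modularity at
  resolution 0.5, t-SNE for visualisation, per-sample/per-condition
  composition tables.
- **Markers**: one-vs-rest Wilcoxon rank-sum per cluster with
  `avg_log2FC = log₂((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1))` and
  Benjamini–Hochberg correction.
- **Cross-species correspondence** (the core): for each shared cell type,
  intersect the top-50 most enriched genes of both species through a 1:1
  ortholog map; z-score pseudobulk profiles over the pooled panel across the
  combined clusters; hierarchical clustering with distance `1 − r` (Pearson,
  average linkage); pair each cluster of species A with its
  highest-correlation cluster of species B.
- **Scoring**: gene-set module scores (plain mean, or mean minus
  expression-matched bin controls), Wilcoxon group comparisons, and
  hypergeometric over-representation against GMT collections.
- **Synthetic data**: a negative-binomial two-species generator
  (`Var = μ + μ²/θ`) with planted cell-type programs shared through
  orthologs, species-private types, condition-dependent composition shifts
  (SMC depletion, immune expansion), mitochondrial content and barcode
  doublets — with the full ground truth returned for validation.

## Worked example

```python
import numpy as np
from orthocell import GeneratorConfig, generate_two_species, lognormalize
from orthocell.markers import all_markers
from orthocell.xspecies import OrthologMap, shared_marker_set, pseudobulk, correspondence

cm_h, cm_m, truth = generate_two_species(GeneratorConfig(seed=3))
nm_h, nm_m = lognormalize(cm_h), lognormalize(cm_m)
lab_h = np.array([truth.cell_labels[c] for c in cm_h.cell_ids])
lab_m = np.array([truth.cell_labels[c] for c in cm_m.cell_ids])

omap = OrthologMap(truth.ortholog_map)
panel = shared_marker_set(all_markers(nm_h, lab_h), all_markers(nm_m, lab_m), omap, n=50)
pb_h = pseudobulk(nm_h, lab_h, panel)
pb_m = pseudobulk(nm_m, lab_m, [omap.a_to_b[g] for g in panel])
pb_m.columns = panel
res = correspondence(pb_h, pb_m, panel, prefix_a="human", prefix_b="mouse")
for t, (match, r) in res.pairing.items():
    print(t, "->", match, round(r, 3))
```

prints

```
EC -> EC 0.962
Fibroblast -> Fibroblast 0.971
Macrophage -> Macrophage 0.971
SMC -> SMC 0.932
TCell -> TCell 0.981
human_private0 -> SMC 0.108
```

Each of the five shared aortic cell types pairs with its mouse namesake at
high Pearson correlation of the scaled pseudobulk profiles; the
species-private type is reported with its best available match at a clearly
lower correlation rather than suppressed.  The full narrative scripts live
in `examples/` (simulation + QC, clustering + markers, correspondence,
scoring + enrichment).

A thin CLI mirrors the library (`orthocell simulate|qc|preprocess|cluster|
markers|xspecies|score|enrich|run`); `orthocell run --config cfg.yaml --out
dir/` executes the whole pipeline from a YAML config and writes a manifest
with per-stage seeds, dimensions and artifact hashes.

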