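# Full-pipeline demo config: simulate a two-species study and run every
# stage (QC -> preprocess -> cluster -> markers -> cross-species -> score).
#   orthocell run --config examples/pipeline_config.yaml --out out/
seed: 7
simulate:
  n_celltypes: 5
  n_private_celltypes: 1
  cells_per_type_per_condition: {control: 100, aneurysm: 100}
  n_ortholog_genes: 1000
  n_species_specific_genes: 100
  n_marker_genes_per_type: 25
  marker_fold_change: 4.0
  baseline_mean: 2.0
  nb_dispersion: 1.0
  mito_gene_count: 13
  mito_mean_pct: 3.0
  doublet_rate: 0.05
n_hvg: 2000
n_pcs: 30
resolution: 0.5
knn_k: 20
top_n_xspecies: 50
annotation: truth
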