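# Full pipeline on a synthetic dataset under the default study conditions.
# Replace `sim:` with `input: {mtx: ..., cells: ..., genes: ...}` to run on
# a real MTX + TSV dataset.
sim:
  n_genes: 2000
  n_samples_per_phenotype: 4
  cells_per_sample_per_subtype: 150
  blur_sm: 0.5
  blur_d1d2: 0.1
species: mouse
min_unique_genes: 500
lfc_min: 0.1
alpha: 0.001
regression_order: 1
regression_ci: 0.99
seed: 1
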