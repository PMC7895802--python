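# Small synthetic configuration: a fast, fully self-contained run of every
# pipeline stage. Sizes are deliberately modest so the whole pipeline runs in
# seconds; statistical performance at these sizes is weaker than at the
# generator defaults.
simulation:
  n_genes: 600
  n_terms: 200
  term_size_range: [15, 40]
  groups:
    long: {n_interventions: 3, n_studies_per_intervention: 2, n_datasets_per_study: 1}
    short: {n_interventions: 3, n_studies_per_intervention: 1, n_datasets_per_study: 2}
    "null": {n_interventions: 6, n_studies_per_intervention: 1, n_datasets_per_study: 1}
  shared_weight: 0.8
  planted_terms: {preset: shared_opposite, n: 10, shift: 2.5}
  base_sd: 1.0
  dataset_noise_sd: 0.5
  se: 0.5
  ageing_mix: 0.8
  tissue: liver
  seed: 20210311
candidate_lambdas: [0.7, -0.7, 0.5, -0.5, 0.3, -0.3]
min_shared: 50
quantile: 0.95
n_perm: 300
n_random: 50000
fdr: 0.05
oc_threshold: 0.4
min_cluster: 5
min_term_size: 5
seed: 20210311
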