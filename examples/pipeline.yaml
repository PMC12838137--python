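# Example pipeline configuration for `envgp run --config examples/pipeline.yaml`.
# A synthetic study is generated (sim block); to analyze real data replace
# `sim` with an `inputs` block of CSV paths (markers, marker_map, catalog,
# weather, phenotypes).
out_dir: pipeline_run
seed: 1
sim:
  n_lines: 80
  n_hybrids: 40
  n_markers: 300
  n_sites: 4
  n_years: 2
  duplicate_count: 3
  sparsity: 0.9
models: [M_1, M_2, M_6]
stages: [blues, cv, cluster, select]
cv:
  runs: 3
  min_genotypes_per_env: 30
mcmc:
  nIter: 1500
  burnIn: 300
clustering:
  k: auto
  min_size: 2
  core_size: 40
selection:
  top_frac: 0.07
  random_frac: 0.03
  adapted_frac: 0.10
  overall_top_n: 10
  rate: 0.32
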