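# Demo pipeline configuration: simulate the study conditions end-to-end.
# Run:  splicemeth all --config configs/demo.yaml --out results/demo
out_dir: results/demo

alpha_die: 0.01
alpha_deu: 0.01
alpha_dm: 0.01
alpha_ks: 0.001
min_count: 2
min_samples: 9
min_coverage: 8
promoter_window: 3000

simulate_mode: true
pooled_ks: true

simulation:
  seed: 1
  n_genes: 300
  n_control: 9
  n_treatment: 10
  n_control_meth: 7
  n_treatment_meth: 9
  die_fraction: 0.1
  die_log2fc: 2.0
  deu_fraction: 0.3
  deu_usage_shift: 4.0
  dm_fraction_background: 0.04
  dm_delta: 0.3
  coupling_enrichment: 5.0
  cpg_density: 2.0
  coverage_mean: 20.0
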