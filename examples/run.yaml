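# End-to-end synthetic run: simulate -> type -> analyse.
# Rerunning with the same seeds reproduces every output byte-for-byte.
outdir: out/demo_run
seeds:
  simulate: 11
  popgen: 12
  distances: 13
simulate:
  library:
    n_alleles: 12
    length: 270
    min_pairwise_diff: 2
  breeds:
    - name: East1
      n_individuals: 40
      freq_model: 2.5        # Ewens theta
    - name: East2
      n_individuals: 40
      freq_model: 2.5
    - name: West1
      n_individuals: 40
      freq_model: 2.5
  reads:
    depth_mean: 32.61
    depth_sd: 18.29
    error_rate: 0.002
  write_fastq: false
typing:
  params:
    min_depth: 10
    balance_threshold: 0.25
    noise_frac: 0.10
popgen:
  n_reps_hwe: 20000
  n_reps_slatkin: 20000
  n_perms_fst: 2000
distances:
  metrics: [DA, Ds]
  tree_metric: DA
  bootstrap_reps: 200
  pca_matrix: covariance
  common_threshold: 0.05
seq_diversity:
  R: 2.0
  mature_start: 6
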