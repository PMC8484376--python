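# End-to-end pipeline configuration for `poolcross run --config examples/cross.yaml`
# Thresholds carry the scan defaults: 30 kb windows, min 10 variants,
# Bonferroni alpha 0.05, Z_Hp cutoff -4.70, marker spacing 189-322 kb.
seed: 17
out_dir: scratch/run

simulate:
  chromosomes:
    - {name: chr1, length_bp: 20000000, rate_cm_per_mb: 4.0}
    - {name: chr11, length_bp: 5000000, rate_cm_per_mb: 4.0}
  causal_locus: [chr11, 4500000]        # MC1R-like pattern locus
  modifier_locus: [chr1, 10000000]      # SOX10/Db-like modifier
  n_backcross: 365
  transmission_distortion: 0.5
  variant_spacing_bp: 2000

pools:
  pool_a: {name: AB, phenotypes: [AB], coverage: 45, error_rate: 0.001}
  pool_b: {name: WT, phenotypes: [WT], coverage: 45, error_rate: 0.001}

scan:
  window_bp: 30000
  min_variants: 10
  alpha: 0.05

hp:
  n_breeds: 6
  pool_size: 5
  coverage: 10
  genome: [{name: chrZ, length_bp: 5000000}]
  ibd_segment: [chrZ, 2400000, 2500000]
  cutoff: -4.70

marker_filter:
  region: [chr11, 1, 5000000]
  freq_range_pool_a: [0.4, 0.6]
  freq_max_pool_b: 0.2
  min_depth: 20
  spacing_range: [189000, 322000]

segregation_ratio: [1, 1]
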