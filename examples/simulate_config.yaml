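# Template config for `nampop simulate -c simulate_config.yaml -o out --seed 1`
genome:
  n_chromosomes: 2
  chrom_length_bp: 100000000
  chrom_length_cm: 100.0
  markers_per_chromosome: 50
sim:
  n_families: 3
  rils_per_family: 50
  generations_of_selfing: 5   # F6 lines
  missing_rate: 0.02
  het_error_rate: 0.005
  ascertainment_fraction: 0.1
founders:
  divergence: 0.5             # per-marker chance a founder differs from the RF
selection:
  - family: fam01
    chromosome: chr1
    position: 50000000
    s: 1.0
    mode: against_alt_hom
trial:
  trait: DB
  mu: 70.0
  locations: 3
  reps: 2
  sigma_g: 1.0
  varcomps: {gl: 0.3, rep: 0.1, col: 0.1, row: 0.1, resid: 1.0}
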