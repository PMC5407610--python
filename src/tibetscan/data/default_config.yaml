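# Default pipeline configuration: the study's thresholds and grids.
demography:
  generation_time: 25.0          # years/generation
  mutation_rate: 1.25e-8         # /bp/generation
  recombination_rate: 1.0e-8     # /bp/generation
  # Fitted two-population model point estimates (diploid sizes, years,
  # per-generation per-chromosome migration).
  nA1: 12804
  nC1: 500
  nC2: 75203
  nC3: 1326988
  nT1: 2445
  nT2: 13292
  nT3: 77743
  T1: 6355
  T2: 44588
  T3: 9419
  m11: 6.8e-4
  m12: 9.0e-4
  m21: 1.3e-11
  m22: 4.0e-7

samples:
  TIB: 27      # diploids, target population
  HAN: 62      # diploids, comparison population

qc:
  quality_threshold: 30
  max_missing_fraction: 0.05
  max_discordance: 0.05
  enriched_target_min: 0.10
  enriched_reference_max: 0.01
  archaic_maf_max: 0.05

cms:
  window_width: 200000
  prior: 1.0e-4
  bins: 60
  pseudocount: 1.0
  ehh_truncation: 0.05
  ihs_daf_range: [0.05, 0.95]
  top_fractions: [0.002, 0.01]
  # sweep-scenario training grid
  selection_coefficients: [0.02, 0.03, 0.04]
  onsets_generations: [0, 100, 200, 300, 400]
  end_frequencies: [0.2, 0.4, 0.6, 0.8]

introgression:
  d_block_size: 1000000
  d_bootstrap_replicates: 200
  dstar_window_width: 200000
  dstar_groups: 20
  sstar_window_width: 50000
  sstar_bonus: 5000
  sstar_mismatch: -10000
  sstar_min_spacing: 10
  sstar_score_threshold: 50000
  sstar_archaic_match_min: 0.3
  overlap_permutations: 10000

archaic_scenario:
  archaic_split_years: 700000
  sampled_vs_introgressor_split_years: 400000
  denisovan_neanderthal_split_years: 450000
  archaic_size: 2500
  denisovan_fraction: 0.004
  denisovan_pulse_years: 40000
  neanderthal_fraction: 0.02
  neanderthal_pulse_years: 55000

dating:
  mu_per_year: 5.0e-10
  survival_threshold: 0.05
  archaic_effective_size: 2580

enrichment:
  replicates: 10000
  top_fraction: 0.002
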