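# Bundled demo configuration for `sedadna run`.
# Small synthetic world: 3 families x 2 genera x 2 species (the last family
# is the contaminant pool used to seed the laboratory controls), 8 dated
# samples along one sediment core, moderate deamination damage, and a
# 6-tip mitochondrial panel placed from two simulated eDNA samples.
seed: 0
taxonomy:
  n_families: 3
  genera_per_family: 2
  species_per_genus: 2
reference_db:
  genome_length: 1000
  divergence: 0.08
fragments:
  mean_len: 55.0
  sd_len: 15.0
  min_len: 30
  max_len: 150
damage:
  p1_ct: 0.25
  lambda_decay: 0.3
  seq_error: 0.002
samples:
  n_samples: 8
  reads_per_sample: 400
  contamination_fraction: 0.05
  core_depth_cm: 200.0
  dated_ages: [500.0, 20500.0]
controls:
  n_controls: 2
  reads_per_control: 120
classify:
  max_mismatches: 2
  rank: genus
  min_reads: 3
  min_samples: 1
authenticate:
  min_terminal_rate: 0.05
  alpha: 0.05
  profile_depth: 25
  max_mismatches: 8
abundance:
  n_sim: 500
community:
  bin_width: 5000.0
  nmds_k: 2
  nmds_starts: 8
  nmds_max_iter: 200
placement:
  enabled: true
  n_tips: 6
  mutations_per_branch: 4
  genome_length: 3000
  coverage: 8.0
  mode: all-sites
  min_markers: 10
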