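# Demo run: a three-lineage simulation (query map, reference genome, second
# query map) plus a three-segment microsynteny comparison on the bundled
# ovate-style fixtures.  Rerunning with the same seed is byte-identical.
seed: 42
output_dir: runs/demo
log_level: INFO

comparison:
  simulation:
    n_chromosomes: 3
    markers_per_chromosome: 20
    mean_gap_bp: 1100000
    n_events_per_lineage: 2
    marker_loss_rate: 0.05
    paralog_rate: 0.02
    n_spurious_multihit: 2
    n_weak_only: 1
    n_split_hsp: 2
    cM_per_Mb_mean: 2.8
    cM_per_Mb_sd: 0.4
    triangulate: true

cascade:
  e_strict: 1.0e-10
  e_primary: 1.0e-6
  hsp_merge_window: 50000

synteny:
  min_markers: 3
  max_gap_target_bp: 3200000
  max_gap_query_cM: 12

microsynteny:
  segments:
    - segments/coffee_ovate.gff3
    - segments/tomato_ovate.gff3
    - segments/grape_ovate.gff3
  family_attribute: family
  allow_reverse_reading: true
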