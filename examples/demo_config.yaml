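seed: 42
output_dir: demo_out
synthetic:
  chromosome_lengths:
  - 26176
  - 14425
  gc_content: 0.4443
  repeats:
  - pair_id: R1
    length: 982
    n_mismatches: 0
    orientation: direct
    placement_1:
    - 0
    - 2001
    placement_2:
    - 1
    - 2001
  - pair_id: R2
    length: 360
    n_mismatches: 0
    orientation: inverted
    placement_1:
    - 0
    - 6001
    placement_2:
    - 1
    - 6001
  - pair_id: R3
    length: 211
    n_mismatches: 0
    orientation: direct
    placement_1:
    - 0
    - 10001
    placement_2:
    - 1
    - 10001
  - pair_id: R4
    length: 137
    n_mismatches: 12
    orientation: direct
    placement_1:
    - 0
    - 14001
    placement_2:
    - 0
    - 20001
  ssrs:
  - motif: A
    copies: 12
    chromosome: 0
    start: 16001
  - motif: TA
    copies: 7
    chromosome: 0
    start: 16501
  - motif: AAG
    copies: 5
    chromosome: 0
    start: 17001
  - motif: A
    copies: 14
    chromosome: 1
    start: 8001
  - motif: TA
    copies: 6
    chromosome: 1
    start: 8501
  tandems:
  - unit_length: 20
    copies: 3
    n_substitutions: 2
    chromosome: 0
    start: 18001
  - unit_length: 25
    copies: 3
    n_substitutions: 3
    chromosome: 1
    start: 9001
  transfers:
  - mito_chromosome: 0
    mito_start: 22000
    mito_end: 23577
    plastid_start: 2001
    n_substitutions: 0
  - mito_chromosome: 0
    mito_start: 24100
    mito_end: 24599
    plastid_start: 5001
    n_substitutions: 0
  - mito_chromosome: 1
    mito_start: 12000
    mito_end: 12399
    plastid_start: 7001
    n_substitutions: 0
  - mito_chromosome: 1
    mito_start: 13000
    mito_end: 13299
    plastid_start: 9001
    n_substitutions: 0
  plastid_length: 15590
reads:
  coverage: 40.0
  read_length_mean: 3000.0
  read_length_sd: 2000.0
  per_base_error_rate: 0.05
  major_weight: 0.5
recombination:
  flank_length: 1000
  min_anchor: 200
  min_identity: 0.8
  min_support: 2
  max_depth: 2
  min_repeat_length: 100
  event_plan:
  - pair: R1
    mode: fusion
    from_major_only: true
  - pair: R3
    mode: fusion
    from_major_only: true
  - pair: R4
    mode: fission
    from_major_only: true
  - pair: R2
    mode: inversion
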