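subject_format:
  prefix: SUB
  site_code: BER
  body_length: 6
  scope: subject
  alphabet: 23456789ABCDEFGHJKLMNPQRSTUVWXYZ
  separator: '-'
  check_scheme: iso7064_mod37_2
  generation_mode: random
biosample_format:
  prefix: BIO
  site_code: BER
  body_length: 6
  scope: biosample
  alphabet: 23456789ABCDEFGHJKLMNPQRSTUVWXYZ
  separator: '-'
  check_scheme: iso7064_mod37_2
  generation_mode: random
identity_schema:
  fields:
  - name: first_name
    kind: text
    required: true
    enum_values: []
    match_weight: 1.0
  - name: last_name
    kind: text
    required: true
    enum_values: []
    match_weight: 1.0
  - name: date_of_birth
    kind: date
    required: true
    enum_values: []
    match_weight: 1.0
  - name: sex
    kind: enum
    required: true
    enum_values:
    - F
    - M
    - X
    match_weight: 0.25
schedule:
- visit_id: BL
  label: Baseline
  order_index: 0
  allowed_sample_types:
  - SER
  - PLA
  - SWB
- visit_id: FU1
  label: Follow-up 1
  order_index: 1
  allowed_sample_types:
  - SER
  - SWB
sample_types:
- code: SER
  label: Serum
- code: PLA
  label: Plasma
- code: SWB
  label: Swab
block_threshold: 0.98
review_threshold: 0.85
backup_interval_days: 1
expected_capacity: 100000
lock_stale_hours: 12.0
rng_seed: null
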