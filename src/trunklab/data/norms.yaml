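# Normative endurance values and category bins (seconds).
# Copy and edit to override the packaged defaults, then load with
# trunklab.norms.load_config(path).
norms:
  steet_range: [62, 131]
  tcset_mean: 134
  sbet_mean: 84
  sbet_sd: 24.5
  flexor_extensor_ref: 0.77
  right_left_ref: 0.96
  side_imbalance_threshold: 0.05
bins:
  STEET:
    - [bad, 0, 61]
    - [good, 62, 131]
    - [perfect, 132, 240]
  TCSET:
    - [bad, 0, 131]
    - [good, 132, 240]
  SBET:
    - [bad, 0, 60]
    - [good, 61, 108]
    - [perfect, 109, 240]
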