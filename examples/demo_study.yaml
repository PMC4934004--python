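# Illustrative 3-group e-diary study (hourly x 48 h style design).
# Generative values are illustrative, not estimates of any real population.
outcome: distress
seed: 20240101
population:
  reference_group: BPD
  # (homebase, autoregressive slope, log within-person variance)
  reference_means: [5.0, 0.3, 0.0]
  between_person_cov:
    - [0.5, 0.0, 0.0]
    - [0.0, 0.02, 0.0]
    - [0.0, 0.0, 0.1]
  group_deltas:
    PD: [-2.0, -0.1, 0.3]
    MD: [-1.3, 0.05, 0.1]
design:
  n_days: 2
  prompts_per_day: 13
  scale_min: 0
  scale_max: 9
  compliance: 0.92
  discretize: false
group_sizes:
  BPD: 25
  PD: 25
  MD: 25
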