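# Full-pipeline demo config: simulate -> preprocess -> fit-freq -> fit-bayes -> report.
# Bayesian chain settings are scaled down for a quick demo; the analysis
# default protocol is 4 chains x (5000 burn-in + 2500 kept).
seed: 13
outcome: distress
reference_group: BPD
pooled_patients: false
exclusion_rules: [zero_variance, linear_trend]
simulate:
  outcome: distress
  population:
    reference_group: BPD
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
    prompts_per_day: 11
    scale_min: 0
    scale_max: 9
    compliance: 0.95
  group_sizes:
    BPD: 10
    PD: 10
    MD: 10
freq:
  n_starts: 3
bayes:
  n_chains: 4
  burn_in: 500
  keep: 500
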