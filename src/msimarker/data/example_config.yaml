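# Demonstration pipeline configuration (small synthetic experiment).
# Omitted keys fall back to package defaults; unknown keys are rejected.
seed: 7
simulate:
  groups: {TAA: 2, AAA: 2, EVAR: 2}
  grid_shape: [16, 16]
  mz_range: [600.0, 1850.0]
  mz_step: 0.05
  decoy_fraction: 0.5
segment:
  n_leaves: 4
discover:
  comparisons:
    - {group_a: EVAR, group_b: TAA, region: media}
    - {group_a: AAA, group_b: TAA, region: media}
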