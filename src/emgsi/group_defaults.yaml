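# Cohort-level parameter distributions for the synthetic sEMG generator.
# selectivity: fraction of intended activation that stays on target
#   (1 = fully selective); drawn uniformly from the stated range per subject.
# mirror_range: contralateral homologous leakage gain range.
# joint_jitter_sd: per-task Gaussian jitter of the subject-level selectivity,
#   giving joint-to-joint variation (and the synthetic ordinal joint scores).
# session_jitter_sd: between-day drift of the true selectivity applied to
#   retest sessions only.
# coactivation_strength: within-leg off-diagonal of the leakage matrix;
#   effective off-target gain is (1 - selectivity) * strength.
control:
  selectivity_range: [0.88, 1.0]
  mirror_range: [0.0, 0.08]
  joint_jitter_sd: 0.04
  session_jitter_sd: 0.04
  coactivation_strength: 0.8
  baseline_noise_uv: 2.0
  mains_amplitude_uv: 0.0
CP:
  selectivity_range: [0.25, 0.9]
  mirror_range: [0.0, 0.5]
  joint_jitter_sd: 0.08
  session_jitter_sd: 0.06
  coactivation_strength: 0.8
  baseline_noise_uv: 2.0
  mains_amplitude_uv: 0.0
reference_adult:
  selectivity_range: [0.93, 1.0]
  mirror_range: [0.0, 0.04]
  joint_jitter_sd: 0.03
  session_jitter_sd: 0.03
  coactivation_strength: 0.8
  baseline_noise_uv: 2.0
  mains_amplitude_uv: 0.0
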