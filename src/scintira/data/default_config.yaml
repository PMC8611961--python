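diagnostics:
  bootstrap_alpha: 0.05
  bootstrap_samples: 2000
  ci_alpha: 0.05
  levene_alpha: 0.05
exclusions:
  areas:
  - knee
  - knee
  - elbow
  n_excluded: 3
oa_cohort:
  activity_mixture:
    typical:
      esr_log_shift: 0.0
      gh_shift: 0.0
      prevalence_scale: 1.0
      proportion: 1.0
      ratio_shift_active: 0.0
      ratio_shift_nonaffected: 0.0
  burden_standardization:
    mean: 1.0
    sd: 1.0
  disease: OA
  esr_coupling:
    ceiling: 120.0
    floor: 2.0
    log_intercept: 2.3
    sigma: 0.3
    z_coef: 0.0
  gh_coupling:
    ceiling: 100.0
    floor: 0.0
    intercept: 30.0
    sigma: 8.0
    z_coef: 0.0
  n_patients: 15
  patient_effect_sd: 0.08
  ratio_distributions:
    non_affected:
      mean: 0.88
      sd: 0.35
    tender:
      mean: 1.94
      sd: 0.9
  ratio_floor: 0.05
  seed: 1
  status_prevalence:
    default:
      both: 0.0
      swollen: 0.0
      tender: 0.061905
ra_cohort:
  activity_mixture:
    high:
      esr_log_shift: 1.398094
      gh_shift: 17.83227
      prevalence_scale: 1.714427
      proportion: 0.215385
      ratio_shift_active: 0.036159
      ratio_shift_nonaffected: 0.25493
    low:
      esr_log_shift: -1.053622
      gh_shift: -10.595107
      prevalence_scale: 0.495217
      proportion: 0.261538
      ratio_shift_active: -0.343652
      ratio_shift_nonaffected: -0.166987
    moderate:
      esr_log_shift: 0.0
      gh_shift: 0.0
      prevalence_scale: 0.885541
      proportion: 0.523077
      ratio_shift_active: -0.130154
      ratio_shift_nonaffected: -0.02
  burden_standardization:
    mean: 7.9766
    sd: 3.6084
  disease: RA
  esr_coupling:
    ceiling: 120.0
    floor: 2.0
    log_intercept: 2.505331
    sigma: 0.22
    z_coef: 0.25
  gh_coupling:
    ceiling: 100.0
    floor: 0.0
    intercept: 43.822539
    sigma: 7.0
    z_coef: 6.0
  n_patients: 65
  patient_effect_sd: 0.15
  ratio_distributions:
    both:
      mean: 1.94
      sd: 1.16
    non_affected:
      mean: 1.12
      sd: 0.49
    swollen:
      mean: 2.07
      sd: 0.92
    tender:
      mean: 1.68
      sd: 0.81
  ratio_floor: 0.05
  seed: 0
  status_prevalence:
    default:
      both: 0.110072
      swollen: 0.024216
      tender: 0.095762
render:
  background_count_level: 10.0
  bone_count_level: 100.0
  hotspot_kernel_sigma: 1.8
  pixel_size_mm:
    foot_left: 2.4
    foot_right: 2.4
    hand_left: 2.4
    hand_right: 2.4
    pelvis_posterior: 2.4
    wholebody_anterior: 6.0
  poisson_noise: true
  seed: 2
  view_shapes:
    foot_left:
    - 96
    - 96
    foot_right:
    - 96
    - 96
    hand_left:
    - 96
    - 96
    hand_right:
    - 96
    - 96
    pelvis_posterior:
    - 96
    - 96
    wholebody_anterior:
    - 220
    - 80
seed: 0
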