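# Five-group study preset: untreated controls, the enzyme-weakened ectatic
# model (KC), and KC treated with cornea- (COR), cartilage- (CART) or
# lymph-node-derived (LN) particle media.
#
# Group values encode the ordinal structure of the measured comparisons
# (KC: least dense packing, largest fibrils, softest, least thermally stable;
# treated groups restored; LN: smallest fibrils at the highest density).
# Fibril densities/diameters are arbitrary but realistic ordinals on a
# benchmarkable scale; denaturation temperatures use the reported group means.
seed: 0
groups: [control, KC, COR, CART, LN]
stages: [tem, tensile, dsc, qpcr]

tem:
  n_images: 3
  field:
    field_width_px: 1024
    field_height_px: 1024
    pixel_size_nm: 2.0
    min_gap_nm: 8.0
    fibril_intensity: 0.2
    background_intensity: 0.8
    noise_sd: 0.02
    blur_sigma_px: 0.7
  group_fields:
    control: {target_density: 40.0, diameter_mean_nm: 32.0, diameter_sd_nm: 5.0}
    KC:      {target_density: 25.0, diameter_mean_nm: 38.0, diameter_sd_nm: 8.0}
    COR:     {target_density: 38.0, diameter_mean_nm: 29.0, diameter_sd_nm: 7.0}
    CART:    {target_density: 36.0, diameter_mean_nm: 32.0, diameter_sd_nm: 5.0}
    LN:      {target_density: 48.0, diameter_mean_nm: 26.0, diameter_sd_nm: 4.0}
  segmentation:
    local_window_px: 51
    offset: 0.22
    min_area_px: 12
    max_area_px: 10000
    min_circularity: 0.6
    connectivity: 8
  density:
    window_px: 300
    n_windows: 200
    min_images: 3
  bin_width_nm: 5.0

tensile:
  n_replicates: 6
  gauge_length_mm: 8.0
  model: toe-exponential
  toe_rate: 8.0
  strip_width_mm: 5.0
  thickness_mm: 0.4
  displacement_rate_mm_s: 0.1
  max_strain: 0.4
  sampling_hz: 10.0
  noise_sd_N: 0.02
  group_toe_amplitude:
    control: 0.060
    KC: 0.035
    COR: 0.055
    CART: 0.045
    LN: 0.045
  fit_lo_frac: 0.7
  fit_hi_frac: 0.9

dsc:
  n_replicates: 3
  peak_width_C: 2.0
  peak_depth_mW: 1.0
  baseline_intercept_mW: 0.5
  baseline_slope_mW_per_C: 0.002
  t_start_C: 10.0
  t_end_C: 95.0
  heating_rate_C_min: 5.0
  sampling_interval_C: 0.1
  noise_sd_mW: 0.02
  group_td:
    control: {mean: 66.80, sd: 0.27}
    KC:      {mean: 62.57, sd: 1.11}
    COR:     {mean: 66.96, sd: 0.28}
    CART:    {mean: 66.08, sd: 0.71}
    LN:      {mean: 66.80, sd: 0.47}

qpcr:
  genes: [Gapdh, Tnfa, Aldh, Keratocan, Biglycan]
  housekeeping: Gapdh
  control_group: control
  replicates_per_group: 6
  ct_noise_sd: 0.25
  baseline_ct:
    Gapdh: 18.0
    Tnfa: 26.0
    Aldh: 24.0
    Keratocan: 25.0
    Biglycan: 23.0
  # log2 fold change vs control: inflammation up and keratocyte markers down
  # in the ectatic model; treated groups restored (Tnfa below control).
  log2_effects:
    KC:   {Tnfa: 2.5, Aldh: -1.5, Keratocan: -1.5, Biglycan: -1.2}
    COR:  {Tnfa: -0.7, Aldh: 0.0, Keratocan: 0.0, Biglycan: 0.0}
    CART: {Tnfa: -0.5, Aldh: -0.2, Keratocan: -0.1, Biglycan: 0.0}
    LN:   {Tnfa: -0.5, Aldh: 0.0, Keratocan: -0.2, Biglycan: 0.0}
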