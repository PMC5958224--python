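# Default configuration: acquisition protocol, simulator baselines, drought
# presets, segmentation, and classification settings. All times in seconds,
# intensities in umol m^-2 s^-1, fluorescence in camera counts.

protocol:
  dark_adapt_end_s: 17.0
  fo_window_start_s: 1.0
  fo_window_duration_ms: 4040.0
  fo_intensity_umol: 0.1
  fm_flash_time_s: 5.56
  flash_duration_ms: 320.0
  flash_intensity_umol: 2300.0
  actinic_on_s: 22.24
  actinic_off_s: 92.24
  actinic_intensity_umol: 100.0
  fp_time_s: 23.12
  light_flash_times_s: [32.24, 42.24, 52.24, 72.24, 92.24]
  dark_flash_times_s: [122.24, 152.24, 182.24]
  frame_rate_hz: 2.0
  flash_frame_rate_hz: 50.0

simulator:
  baseline:
    fm_amp: 1000.0        # dark-adapted maximal fluorescence, counts
    fvfm_true: 0.85       # sets Fo = fm_amp * (1 - fvfm_true)
    npq_ss: 1.2
    phi_ss: 0.55
    phi0: 0.05            # PSII yield right at light onset (Kautsky peak)
    k_ind: 0.25           # NPQ induction rate, 1/s
    k_rel: 0.08           # NPQ dark-relaxation rate, 1/s
    k_p: 0.35             # photochemical induction rate, 1/s
    band_em:              # UV-excited band emissions, counts
      BF: 200.0
      GF: 300.0
      RF: 600.0
      IrF: 400.0
  noise:
    read_sd: 2.0
    shot_scale: 0.5
  rosette:
    image_shape: [48, 48]
    n_leaves: 8
    leaf_length_px: [7, 10]
    leaf_width_px: [2.5, 4]

# Drought severity presets. Multipliers scale the baseline physiology; the
# control preset is all-ones. Magnitudes are calibration choices that encode
# the qualitative day-by-day ordering (weak at day 1, strong at days 7-8)
# and the reported directions of change (NPQ down, PSII yield down, blue and
# green emission up, far-red emission down under drought).
presets:
  control:
    day: 0
    multipliers: {fvfm_true: 1.0, npq_ss: 1.0, phi_ss: 1.0, BF: 1.0, GF: 1.0, RF: 1.0, IrF: 1.0}
    edge_gradient: 0.0
    between_plant_sd: 0.04
  day1:
    day: 1
    multipliers: {fvfm_true: 0.995, npq_ss: 0.98, phi_ss: 0.98, BF: 1.02, GF: 1.02, RF: 1.01, IrF: 0.98}
    edge_gradient: 0.02
    between_plant_sd: 0.04
  day3:
    day: 3
    multipliers: {fvfm_true: 0.985, npq_ss: 0.955, phi_ss: 0.955, BF: 1.045, GF: 1.045, RF: 1.02, IrF: 0.955}
    edge_gradient: 0.05
    between_plant_sd: 0.04
  day5:
    day: 5
    multipliers: {fvfm_true: 0.96, npq_ss: 0.85, phi_ss: 0.85, BF: 1.15, GF: 1.12, RF: 1.08, IrF: 0.85}
    edge_gradient: 0.1
    between_plant_sd: 0.04
  day7:
    day: 7
    multipliers: {fvfm_true: 0.80, npq_ss: 0.55, phi_ss: 0.55, BF: 1.45, GF: 1.40, RF: 1.25, IrF: 0.65}
    edge_gradient: 0.2
    between_plant_sd: 0.04
  day8:
    day: 8
    multipliers: {fvfm_true: 0.72, npq_ss: 0.48, phi_ss: 0.48, BF: 1.55, GF: 1.50, RF: 1.30, IrF: 0.58}
    edge_gradient: 0.25
    between_plant_sd: 0.04

preset_aliases:
  moderate: day3
  severe: day7

segmentation:
  method: otsu
  threshold: 50.0
  min_object_px: 50
  reference: Fm

classification:
  n_features: 9
  folds: 10
  svm_c: 1.0

mda:
  epsilon_mm_cm: 155.0
  path_cm: 1.0
  assay_volume_ml: 2.0
  extract_volume_ml: 5.0
  aliquot_ml: 1.0
  fresh_weight_g: 0.1
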