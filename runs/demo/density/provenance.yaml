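config:
  association:
    count_pseudocount: 1.0
    density_pseudocount: 0.0001
    infection_form: log_ratio
    n_drn_animals: 4
    n_mrn_animals: 3
    noise_cv: 0.1
  cohort:
    densities:
      EPL: 0.0007
      GCL: 0.0008
      GL: 0.014
    n_animals: 3
  coloc:
    cutoff_um: 12.0
    density_um2_per_100um2: 1.5
    jitter_sd_um: 0.3
    max_shift_px: 50
    n_samples: 20
    sample_side_um: 120.0
    shared_fraction: 0.8
  density:
    k: 6.0
  fiber:
    density_tolerance: 0.1
    fiber_amplitude: 600.0
    fiber_length_um: 1.0
    fiber_width_um: 0.7
    render: puncta
    step_length_um: 2.0
    turn_sd: 0.35
  geometry:
    layer_radii_um:
    - 250.0
    - 430.0
    - 610.0
  noise:
    background:
    - 100.0
    - 40.0
    - 25.0
    gaussian_sd: 30.0
    impulse_amplitude: 4000.0
    speckle_rate: 0.0005
  plot: true
  preprocess:
    ball_radius_um: 30.0
    despeckle_window: 3
  resolution: 7.0
  sampling:
    max_attempts_per_sector: 1000
    n_per_layer: 10
    roi_side_um: 120.0
    sector_deg: 36.0
  seed: 13
package: fiberlayer
stage: density
version: 0.1.0
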