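# Reference benchmark: backlit (twin-Fresnel) illumination regime.
# Corner falloff below half of centre plus concentric ring modulation; the
# bednet is crossed once by the imaging light, with per-pass attenuation set
# so the bednet region sits near 40 greyscales, as in the RRS scene.
seed: 0
out_dir: "."
log_level: INFO
scene:
  n_frames: 2500
  illumination:
    mode: backlit
    base_level: 200.0
    corner_falloff_fraction: 0.40
    ring_modulation_amplitude: 30.0
    ring_period_px: 64.0
    net_contrast_factor: 0.45
  geometry:
    image_size: [256, 256]
    bednet_polygon: [[2, 118], [254, 118], [254, 198], [2, 198]]
    bednet_attenuation_per_pass: 0.2
    n_passes: 1
    px_scale_mm: 0.5
  flight:
    n_mosquitoes: 10
    speed_mean_mm_s: 300.0
    turn_sd_rad: 0.12
    frame_rate_hz: 50.0
    home_range_px: 40.0
    release_points: [[38, 64], [115, 52], [192, 64], [244, 40], [70, 226], [200, 232], [52, 158], [115, 166], [178, 158], [238, 166]]
    blob_length_px: 20.0
    blob_width_px: 14.0
  contrast:
    background: [3.0, 5.0]
    front_of_net: [2.0, 3.0]
    behind_net: [1.0, 2.0]
  noise:
    relative_sd: 0.0184
segmentation:
  frame_lag_i: 5
  ksize: 15
  denoise_enabled: true
  region_threshold: 50.0
  bright_threshold: 3.0
  dark_threshold: 1.0
  dilation_px: 5
  min_area_px: 4.0
  max_area_px: 2000.0
tracking:
  max_link_dist_px: 40.0
  frame_rate_hz: 50.0
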