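input_path: /tmp/pytest-of-root/pytest-6/test_localization_csv_input_re0/locs.csv
input_kind: localizations
out_dir: smdwell_out
seed: 0
pixel_nm: 220.0
frame_interval_s: 1.0
n_frames: null
image_shape: null
k_sigma: 5.0
roi_px: 7
psf_sigma_px: 1.3
fit_sigma: false
bg_window_px: 15
max_subtraction_rounds: 2
correct_drift: true
drift_block_frames: 250
drift_zoom: 5
link_radius_px: 1.0
max_gap_frames: 1
sr_zoom: 5
mask_path: null
blur_sigma: 2.0
threshold_method: otsu
dilation_px: 2
min_area_px: 20
margin_px: 2
m_candidates:
- 1
- 2
- 3
bin_width_s: null
bleach_lifetimes_s:
- 195.0
- 1100.0
bleach_weights:
- 0.5
- 0.5
bleach_rel_tol: 0.35
min_events_per_region: 50
kcat_range_per_s:
- 2.0
- 11.0
step_nm: 1.0
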