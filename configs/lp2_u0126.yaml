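lobe_preset: lp2
n_original_ducts:
- 5
- 6
initial_bud_length_um: 22.0
elongation_rate_um_h: 9.1
generation_rate_multipliers:
- 1.0
tip_branch_hazard_per_h: 0.007200000000000001
lateral_hazard_per_h_per_100um: 0.0
event_type_probs:
- 0.55
- 0.08
- 0.37
max_generation: 3
duration_h: 90.0
frame_interval_min: 30.0
treatment: u0126
seed: 0
pixel_size_um: 2.0
duct_width_um: 8.0
field_size_px:
- 1024
- 1024
noise_sigma: 0.0
step_um: 2.0
waviness_rad: 0.04
max_deviation_rad: 0.5
clearance_um: 20.0
junction_exempt_um: 30.0
anchor_margin_um: 60.0
fan_half_angle_rad: 0.45
duct_spacing_um: 120.0
max_events: 5000
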