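n_cells_per_group: 200
speed_median:
  control: 5.73
  uniform: 5.73
  in-field: 5.73
  out-of-field: 5.73
speed_log_sigma:
  control: 0.7808053591078751
  uniform: 0.7808053591078751
  in-field: 0.7808053591078751
  out-of-field: 0.7808053591078751
persistence:
  control: 0.0
  uniform: 0.0
  in-field: 0.0
  out-of-field: 0.0
n_replicates: 3
n_frames: 97
frame_interval: 15.0
dish:
  diameter: 60.0
  boundary_x: 0.0
  exclusion_half_width: 10.0
  penumbra_sigma: 1.0
  nominal_dose: 2.0
fucci_distribution:
  control:
  - 0.4
  - 0.15
  - 0.45
  cisplatin:
  - 0.2
  - 0.097
  - 0.703
seed: 0
step_law: fixed_length
cell_radius: 5.0
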