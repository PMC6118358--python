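# Desk-scale six-round sequential imaging experiment (three rounds per target).
scene:
  field_size_um: [6.8, 6.8]
  seed: 1
  structures:
    - {type: cluster, target_id: clathrin, n: 30, mean_sites: 40}
    - {type: filament, target_id: tubulin, n: 6, length: 4.0}
camera:
  frame_shape: [64, 64]      # pixel_size defaults to 0.1067 um
photophysics:
  p_on: 0.0008               # per-frame activation probability
  photons_per_frame: 800.0
rounds:
  - {target_id: clathrin, carryover_residual: 0.0}
  - {target_id: tubulin,  carryover_residual: 0.02}
  - {target_id: clathrin, carryover_residual: 0.05}
  - {target_id: tubulin,  carryover_residual: 0.02}
  - {target_id: clathrin, carryover_residual: 0.05}
  - {target_id: tubulin,  carryover_residual: 0.02}
kinetics:
  k_disp: 1.0e5              # 1/M/s, 8-nt toehold scale
  invader_conc: "4.87 uM"
  residual_fraction: 0.05
  t_invader: 20.0
n_frames: 2000
seed: 7
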