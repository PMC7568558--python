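# Demo pipeline run: one scaled-down field of view, rendered and analysed
# end to end.  `nk3d run --config examples/demo_run.yaml --out demo_out`
scene:
  n_nk: 25
  n_k562: 0
  motile_fraction: 0.292
  volume: 17742240.0   # 333 x 333 x 160 µm box
  depth: 160.0
  duration: 0.0833333333333  # 5 min
  frame_interval: 30.0
  seed: 1
render: true
pixel_size: 0.65
z_step: 10.0
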