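# Desk-scale pipeline configuration: 60 x 60 cm wall at 6.4 px/cm
# (384 px frame, 6 x 6 grid of 64 px tiles). The full-scale defaults
# (25.6 px/cm, 256 px tiles, levels 4, 64 base channels, 500 epochs)
# apply when a block is omitted.
frame:
  resolution_px_per_cm: 6.4
model:
  levels: 3
  base_channels: 8
  input_px: 64
train:
  epochs: 20
  batch_size: 8
  learning_rate: 0.001
  seed: 0
augment:
  rotation_deg_range: [-15.0, 15.0]
  scale_range: [0.9, 1.1]
  flip_horizontal: true
  intensity_range: [0.8, 1.2]
  gamma_range: [0.7, 1.4]
  chroma_range: [0.8, 1.2]
  seed: 0
synth:
  n_roots: 12
  depth_law: {kind: truncated_exponential, rate_per_cm: 0.1}
  seed: 0
seed: 0
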