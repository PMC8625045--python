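# Reduced-scale study configuration: quarter-scale geometry, small network.
grid:
  N: 64
sensors:
  Ns: 75
  Nt: 64
mask:
  width: 0.34
  orientation: main
kb:
  m: 2
  gamma: 3.0
  radius_in_pixels: 2.0
truncation:
  sigma_star: 1.0e-3
  relative: true
dataset:
  n: 200
  sigma: 0.01
network:
  depth: 1
  base_channels: 16
  dtype: float32
training:
  lr: 0.01
  gamma: 0.1
  epochs: 5
  batch_size: 8
regularizer:
  beta: 15.0
  eps: 1.0e-3
study:
  n_test_phantoms: 10
  noise_levels: [0.0, 0.01, 0.1]
  test_seed: 915148001
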