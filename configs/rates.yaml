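# Convergence-rate toy experiment: quadratic regularizer, source condition
# satisfied, alpha proportional to the noise norm.
rates:
  n_modes: 12
  decay: 0.5
  eps_schedule: [1.0e-1, 3.16e-2, 1.0e-2, 3.16e-3, 1.0e-3, 3.16e-4, 1.0e-4]
  alpha_scale: 1.0
  replications: 20
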