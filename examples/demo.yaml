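# Demo run: a 1.75 m participant, default controller constants, and a
# moderately skilled synthetic user performing one 60 s trial.
participant:
  body_height: 1.75

constants:
  a_max: 0.4
  a_min: 0.1
  hip_disp_min: 0.02
  weight_shift_tol: 0.15

simulation:
  duration: 60.0
  rate: 90.0
  seed: 42

skill:
  thrust_sd: 0.04
  shift_noise_sd: 0.01
  shift_hold_reliability: 0.9
  trunk_mean: 25.0
  trunk_sd: 5.0
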