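# Amide/carboxylate region (1500-1700 cm^-1): amide C=O (1654) responds to
# heating before the residual carboxylate COO- (1583) and before the HOH
# bending of adsorbed water (1635), emulating a well-reticulated sponge in
# which water pockets shield the HOH mode.  Vector normalization: the
# internal-standard band lies outside this window.
synthetic:
  t_min: 250.0
  t_max: 340.0
  t_step: 10.0
  nu_min: 1500.0
  nu_max: 1700.0
  nu_step: 4.0
  noise_sigma: 0.0
  seed: 0
  bands:
    - {center: 1583.0, width: 12.0, shape: gaussian, base_amplitude: 0.7,
       delta_amplitude: -0.12, response: sigmoid, onset_T: 305.0, response_width: 8.0}
    - {center: 1596.0, width: 12.0, shape: gaussian, base_amplitude: 0.65,
       delta_amplitude: 0.0, response: sigmoid, onset_T: 295.0, response_width: 8.0}
    - {center: 1635.0, width: 14.0, shape: gaussian, base_amplitude: 0.45,
       delta_amplitude: 0.10, response: sigmoid, onset_T: 315.0, response_width: 8.0}
    - {center: 1654.0, width: 12.0, shape: gaussian, base_amplitude: 0.9,
       delta_amplitude: 0.20, response: sigmoid, onset_T: 278.0, response_width: 8.0}
region: [1500.0, 1700.0]
reference_mode: first
normalize:
  mode: vector
  window: [1045.0, 1065.0]
baseline: linear_endpoints
threshold_frac: 0.05
sign_epsilon: 0.05
min_separation: 8.0
slices: [1583.0, 1635.0]
outdir: demo_amide
seed: 0
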