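# High-frequency O-H / N-H stretching region (2680-3780 cm^-1): broad,
# heavily overlapped hydrogen-bond bands.  Intrachain hydrogen bonds and
# bonded N-H respond before interchain hydrogen bonds in this emulation.
# Vector normalization (internal standard outside the window).
synthetic:
  t_min: 250.0
  t_max: 340.0
  t_step: 10.0
  nu_min: 2680.0
  nu_max: 3780.0
  nu_step: 4.0
  noise_sigma: 0.0
  seed: 0
  bands:
    - {center: 2900.0, width: 60.0, shape: gaussian, base_amplitude: 0.5,
       delta_amplitude: 0.0, response: sigmoid, onset_T: 295.0, response_width: 8.0}
    - {center: 3254.0, width: 45.0, shape: gaussian, base_amplitude: 0.7,
       delta_amplitude: -0.14, response: sigmoid, onset_T: 315.0, response_width: 8.0}
    - {center: 3347.0, width: 40.0, shape: gaussian, base_amplitude: 0.8,
       delta_amplitude: -0.16, response: sigmoid, onset_T: 275.0, response_width: 8.0}
    - {center: 3560.0, width: 55.0, shape: gaussian, base_amplitude: 0.4,
       delta_amplitude: 0.08, response: sigmoid, onset_T: 295.0, response_width: 8.0}
region: [2680.0, 3780.0]
reference_mode: first
normalize:
  mode: vector
  window: [1045.0, 1065.0]
baseline: linear_endpoints
threshold_frac: 0.05
sign_epsilon: 0.05
min_separation: 20.0
slices: [3254.0, 3347.0]
outdir: demo_hydroxyl
seed: 0
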