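# Fingerprint region (900-1200 cm^-1) of a cellulose nano-sponge look-alike.
# Bands: glycoside/CH-rocking/C-N/C-OH/C-O-C/C-C modes with staggered sigmoid
# onsets so that terminal C-N units (1021) and secondary-alcohol C-OH (1055
# neighbourhood) respond first and the CH rocking mode (992) last.  The
# 1055 cm^-1 internal-standard band itself is held temperature-invariant and
# anchors the band-area normalization.
synthetic:
  t_min: 250.0
  t_max: 340.0
  t_step: 10.0
  nu_min: 900.0
  nu_max: 1200.0
  nu_step: 4.0
  noise_sigma: 0.0
  seed: 0
  bands:
    - {center: 992.0, width: 9.0, shape: gaussian, base_amplitude: 0.6,
       delta_amplitude: 0.12, response: sigmoid, onset_T: 320.0, response_width: 8.0}
    - {center: 1021.0, width: 8.0, shape: gaussian, base_amplitude: 0.4,
       delta_amplitude: 0.10, response: sigmoid, onset_T: 270.0, response_width: 8.0}
    - {center: 1031.0, width: 9.0, shape: gaussian, base_amplitude: 0.9,
       delta_amplitude: 0.18, response: sigmoid, onset_T: 282.0, response_width: 8.0}
    - {center: 1055.0, width: 9.0, shape: gaussian, base_amplitude: 0.8,
       delta_amplitude: 0.0, response: sigmoid, onset_T: 295.0, response_width: 8.0}
    - {center: 1108.0, width: 10.0, shape: gaussian, base_amplitude: 0.5,
       delta_amplitude: 0.10, response: sigmoid, onset_T: 300.0, response_width: 8.0}
    - {center: 1161.0, width: 10.0, shape: gaussian, base_amplitude: 0.35,
       delta_amplitude: 0.07, response: sigmoid, onset_T: 308.0, response_width: 8.0}
region: [900.0, 1200.0]
reference_mode: first
normalize:
  mode: band_area
  window: [1045.0, 1065.0]
baseline: linear_endpoints
threshold_frac: 0.05
sign_epsilon: 0.05
min_separation: 8.0
slices: [992.0, 1021.0, 1049.0]
outdir: demo_fingerprint
seed: 0
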