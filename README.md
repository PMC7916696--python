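# noda2d

Generalized two-dimensional correlation spectroscopy (2D-COS) for
perturbation-indexed series of 1D spectra, built around the discrete
Hilbert–Noda transform.

## The problem

Temperature-dependent FTIR-ATR series of complex materials — here the
motivating system is a cellulose nano-sponge (TEMPO-oxidized, ultrasonicated
cellulose nanofibers cross-linked with branched polyethyleneimine) — contain
heavily overlapped vibrational bands whose intensities respond to heating at
different temperatures. Spreading the series over a second spectral dimension
by cross-correlation both resolves overlapped contributions and, through the
signs of the resulting cross-peaks, reveals **which band responds to the
perturbation first**. `noda2d` implements that full workflow for anyone with
a wavenumber-vs-temperature table of absorbances: spectroscopists ordering
hydrogen-bond or conformational events, and method developers who need a
tested, deterministic 2D-COS core.

## The method

Given k spectra I(ν, Tᵢ) on a common wavenumber grid, with a reference
spectrum Ī(ν) (default: the spectrum at T_min),

- dynamic spectra:  Ĩ(ν, T) = I(ν, T) − Ī(ν)
- synchronous map:  Θ(ν₁, ν₂) = 1/(k−1) · Σᵢ Ĩ(ν₁, Tᵢ) Ĩ(ν₂, Tᵢ)
- asynchronous map: Ω(ν₁, ν₂) = 1/(k−1) · Σᵢ Ĩ(ν₁, Tᵢ) · Σⱼ M<sub>ij</sub> Ĩ(ν₂, Tⱼ)

where M is the Hilbert–Noda matrix, M<sub>ij</sub> = 0 for i = j and
1/(π(j−i)) otherwise — the discrete Hilbert transform along the perturbation
index. Θ is symmetric (auto-peaks on its diagonal measure each band's overall
susceptibility); Ω is antisymmetric with zero diagonal and vanishes for bands
that change strictly in proportion.

Noda's sign rules turn a cross-peak's sign pair into a temporal verdict:
Θ(ν₁,ν₂) > 0 and Ω(ν₁,ν₂) > 0 means ν₁ responds **before** ν₂; Ω < 0 reverses
it; a negative Θ reverses the rule again; Ω ≈ 0 means the two bands respond in
phase. The package detects auto- and cross-peaks, applies these rules, closes
the pairwise verdicts transitively where consistent (cycles are reported, not
resolved), and extracts horizontal asynchronous-map slices at chosen ν₂.

Because no laboratory dataset accompanies the method, the package ships a
synthetic generator: Gaussian/Lorentzian bands whose amplitudes follow
sigmoid (or linear) temperature responses with band-specific onset
temperatures, on the standard 250–340 K, 10 K step, 4 cm⁻¹ acquisition grid.
The onsets define an exact ground-truth ordering against which the inference
is scored.

## Worked example

```python
from noda2d import (BandSpec, SyntheticSpec, generate_series, correlate,
                    detect_autopeaks, detect_crosspeaks, apply_noda_rules,
                    recover_order)

bands = (
    BandSpec(center=1021.0, width=9.0, delta_amplitude=0.15, onset_T=270.0, response_width=8.0),
    BandSpec(center=1055.0, width=9.0, delta_amplitude=0.15, onset_T=290.0, response_width=8.0),
    BandSpec(center=1108.0, width=10.0, delta_amplitude=0.15, onset_T=310.0, response_width=8.0),
)
series, truth = generate_series(SyntheticSpec(bands=bands, nu_min=960.0, nu_max=1170.0))
maps = correlate(series, reference_mode="first")
cps = detect_crosspeaks(maps)
order = apply_noda_rules(cps)
report = recover_order(order, truth)
```

printing the detected peaks and verdicts gives

```
10 spectra x 53 channels, T = 250..340 K
AP  (1020,1020)  Theta = 1.382e-02
AP  (1056,1056)  Theta = 1.138e-02
AP  (1108,1108)  Theta = 6.787e-03
CP  (1056,1020)  signs (Theta,Omega) = (+,-)
CP  (1108,1020)  signs (Theta,Omega) = (+,-)
CP  (1108,1056)  signs (Theta,Omega) = (+,-)
1020 cm^-1 changes prior to 1056 cm^-1
1020 cm^-1 changes prior to 1108 cm^-1
1056 cm^-1 changes prior to 1108 cm^-1
ground-truth recovery: 3/3
```

Three auto-peaks appear at the (grid-snapped) band centres; every cross-peak
has Θ > 0 (all bands grow on heating) and Ω < 0, so in each pair the ν₂ band
— the one with the lower onset temperature — is declared to change first.
The inferred ordering 1021 → 1055 → 1108 cm⁻¹ reproduces the generator's
onset ordering 270 → 290 → 310 K exactly.

## Command line

```sh
noda2d simulate  --config cfg.yaml --out series.csv --seed 1
noda2d correlate --input series.csv --outdir maps/
noda2d peaks     --input series.csv
noda2d order     --input series.csv
noda2d slice     --input series.csv --nu2 992 --nu2 1021
noda2d run       --config cfg.yaml            # full pipeline
noda2d demo      --name fingerprint           # packaged demo regions
```

`noda2d run` writes the artifact bundle: the (re)generated and preprocessed
series, both maps as labelled CSV matrices and one compressed `.npz`
container, peak and ordering tables, a human-readable report, slice CSVs,
contour figures, and a `run_log.yaml` containing the package version and the
complete config — the log alone suffices to replay the run. Identical config
and seed give byte-identical CSVs. Three demo configs (`fingerprint`,
`amide`, `hydroxyl`) emulate the fingerprint (900–1200 cm⁻¹),
amide/carboxylate (1500–1700 cm⁻¹) and O–H/N–H stretching (2680–3780 cm⁻¹)
regions of the cellulose nano-sponge system.

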