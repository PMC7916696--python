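# Methods

## Model

The analysis operates on a k × n matrix of intensities I(ν, T): n wavenumber
channels (cm⁻¹, stored strictly ascending), k acquisitions ordered along an
increasing perturbation trajectory (temperature, K). The correlation
formalism assumes (i) a common wavenumber grid across acquisitions and
(ii) equal spacing along the perturbation axis. The first is enforced by the
container; the second is restored, when violated, by linear interpolation of
each channel onto a uniform temperature grid with the same endpoints and the
same k (curve-fitting resampling is deliberately out of scope). A series that
is already uniform passes through bit-identically.

Dynamic spectra are Ĩ(ν, T) = I(ν, T) − Ī(ν). The reference Ī is, in this
formalism, an arbitrary choice; all standard options are implemented
(`first`, `last`, `mean`, `zero`, integer index), with `first` — the spectrum
at T_min — as the default, so that correlation signs read as responses to an
*upward* temperature trajectory. With `zero`, Ĩ = I exactly.

The synchronous map Θ = ĨᵀĨ/(k−1) is symmetrized after the product; the
asynchronous map Ω = Ĩᵀ(MĨ)/(k−1), with M the discrete Hilbert–Noda matrix
(zero diagonal, 1/(π(j−i)) off it), is antisymmetrized and its diagonal
pinned to exact zero — both are identities in exact arithmetic (to ~1e−16
relative in floats) and pinning them makes the invariants exact rather than
approximate. The discrete matrix is used verbatim; no FFT-based continuous
Hilbert transform is substituted, so results follow the standard published
computation route. The 1/(k−1) normalization sits once outside both sums;
variants in the literature that normalize differently rescale Ω by a
constant and change no sign, hence no verdict.

A k = 2 asynchronous map is computed but emits a warning: the inner Hilbert
term then hinges on a single pair and sequential inference from it is
unreliable. Maps are dense; a guard warns above 5000 channels (two dense
n × n float64 maps ≈ 400 MB).

## Preprocessing

Preprocessing order is region → baseline → normalization. Baseline
correction (`linear_endpoints`) subtracts, per spectrum, the straight line
through the first and last grid points of the *current* region, which is why
it follows region selection; endpoints are exactly zero afterwards.
Normalization offers `band_area` (divide by the trapezoidal area of an
internal-standard window, default 1045–1065 cm⁻¹ around the
oxidation-insensitive cellulose backbone band), `vector` (unit Euclidean
norm) and `none`. Band-area against a genuinely temperature-invariant
standard preserves response ordering; `vector` rescales each spectrum by a
T-dependent norm and can distort or even invert apparent sequences when the
total intensity itself responds — it is provided for cross-sample
comparability, not recommended before sequential-order inference. No
smoothing is implemented anywhere, by design.

## Synthetic generator

The generator emulates a temperature-perturbation FTIR-ATR acquisition:
250–340 K in 10 K steps (k = 10, both endpoints included) on a 4 cm⁻¹ grid,
with bands at the positions catalogued for the cellulose nano-sponge system.
Each band is a unit-height Gaussian or Lorentzian line shape (`width` is the
HWHM) whose amplitude evolves as base + delta · r(T). The canonical delayed
response is the logistic sigmoid r(T) = 1/(1+exp(−(T−T_onset)/w)) — the
field describes onsets without committing to a functional form, and the
sigmoid gives each band a single interpretable onset temperature; a linear
ramp is the in-phase, no-lag control. Default delta is about 20% of the base
amplitude in the packaged configs, a free choice documented here (the
magnitude of real temperature-induced changes is instrument- and
sample-specific); noise is i.i.d. Gaussian per grid point with default σ = 0.

What the generator does **not** model: ATR penetration-depth dispersion,
band-centre drift with temperature, anharmonicity, correlated (pink)
instrument noise, atmospheric lines. Passing tests therefore demonstrate
that the machinery recovers orderings encoded as amplitude responses on a
stationary band structure — not robustness to frequency shifts, which
produce genuine derivative-shaped 2D patterns of their own.

Ground truth: for each pair of responding bands (delta ≠ 0), the band with
the lower onset is `before`; `simultaneous` requires identical onset *and*
identical response shape, which keeps the truth relation well-defined; a
linear band's effective onset is the midpoint of the temperature range (its
response is symmetric about it). Equal onsets with different shapes have no
defined order and produce no truth pair. Truth derives from band parameters
only, never from the noisy matrix.

## Peak detection and sign classification

Auto-peaks are local maxima of the Θ diagonal above `threshold_frac`
(default 0.05) of the diagonal maximum. Cross-peaks are local extrema of
|Θ| and |Ω| in the lower triangle ν₁ > ν₂ (the upper triangle is the mirror
image), at least `min_separation` (default 2 grid steps) off the diagonal;
candidates from the two maps closer than `min_separation` merge,
strongest-normalized first. Peak positions snap to the grid — the maps carry
no information below the acquisition resolution, so sub-grid interpolation
would be decoration.

Sign classification uses `sign_epsilon` (default 0.05): |value| below that
fraction of the map's maximum reads as `~0`. The choice is a made-explicit
version of the qualitative "absence of a cross-peak" reasoning the method
traditionally applies by eye; it is configurable. Two numerical guards: a
map whose maximum is 1e−9 below the other map's is floating-point residue
(e.g. Ω for perfectly in-phase data) and is treated as identically zero,
both in detection and in sign classification.

Verdicts follow the sign-rule table (see README); transitive closure over
shared band coordinates is attempted only when the directed "responds
before" graph is acyclic — cycles are listed in the output and never
auto-resolved, because the pairwise statements are the method's actual
deliverable and a forced total order would overstate them. Whether closure
across pairs with differing Θ signs is legitimate is genuinely open; inferred
relations are therefore explicitly tagged `transitive`.

The recovery harness matches each truth pair to the nearest inferred
relation within `match_tol` = 8 cm⁻¹ (two grid steps — generator centres need
not sit on the grid) in either orientation and scores match / mismatch /
undetected; the recovery fraction is matches over truth pairs, vacuously 1
for an empty truth.

## Benchmark sizes

The standing benchmark is three Gaussian bands (HWHM 10 cm⁻¹) 50 cm⁻¹ apart
— five half-widths, so cross-peaks are clean — with onsets 270/290/310 K
(2.5 response-widths apart) on the k = 10 acquisition, ~50 channels. The
noisy variant adds σ = 1% of the maximum dynamic amplitude and runs 100
seeds; the whole acceptance script completes in a few seconds on one core.

## Known limitations

- Sequential verdicts are only as good as the sign of Ω at the detected
  coordinate; strongly overlapped bands (≲ 1 half-width apart) fuse their
  cross-peaks and the snapped coordinate may sit between the true pair.
- The in-phase verdict (`~0` asynchronous intensity) is threshold-dependent;
  near-simultaneous onsets degrade gracefully into `in_phase` rather than
  producing a wrong direction, which is the intended failure mode.
- Uneven temperature grids are linearized by interpolation; strongly curved
  channel responses between widely spaced acquisitions bias both maps.
- No hetero-spectral correlation, moving-window analysis, or Pareto-type
  scaling; one perturbation variable, one probe.
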