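"""Synthetic temperature-series spectra with a known response ordering.

Real temperature-perturbation FTIR-ATR series of the cellulose nano-sponge
study system are not publicly deposited, so every downstream stage of the
package is exercised on generated look-alikes: a sum of Gaussian/Lorentzian
bands whose amplitudes respond to temperature with band-specific onsets.
Because each band's onset temperature is a generator parameter, the true
"changes-before" ordering of the bands is known exactly and can serve as the
oracle that sequential-order inference is judged against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .spectra_io import SpectralSeries

__all__ = ["BandSpec", "SyntheticSpec", "GroundTruth", "band_profile", "generate_series"]


@dataclass(frozen=True)
class BandSpec:
    """One spectral band and its temperature response.

    The line shape has unit height at ``center`` and half-width-at-half-
    maximum ``width``; its amplitude evolves as

        amplitude(T) = base_amplitude + delta_amplitude * r(T)

    with the response fraction r(T) in [0, 1]:

    * ``sigmoid``: r(T) = 1 / (1 + exp(-(T - onset_T) / response_width)),
      a delayed response whose midpoint sits at ``onset_T``;
    * ``linear``: r(T) = (T - t_min) / (t_max - t_min), the in-phase,
      no-lag control.

    ``delta_amplitude`` is signed: negative means the band loses intensity
    on heating.
    """

    center: float
    width: float
    shape: str = "gaussian"  # gaussian | lorentzian
    base_amplitude: float = 1.0
    delta_amplitude: float = 0.0
    response: str = "sigmoid"  # sigmoid | linear
    onset_T: float = 295.0
    response_width: float = 10.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.response_width <= 0:
            raise ValueError(f"response_width must be > 0, got {self.response_width}")
        if self.base_amplitude < 0:
            raise ValueError(f"base_amplitude must be >= 0, got {self.base_amplitude}")
        if self.base_amplitude + self.delta_amplitude < 0:
            raise ValueError(
                "base_amplitude + delta_amplitude must be >= 0 "
                "(absorbance never goes negative)"
            )
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown line shape {self.shape!r}")
        if self.response not in ("sigmoid", "linear"):
            raise ValueError(f"unknown response {self.response!r}")

    @property
    def responds(self) -> bool:
        return self.delta_amplitude != 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a generated temperature series.

    Defaults mirror the acquisition design of the emulated experiment:
    temperatures 250-340 K in 10 K steps (k = 10 spectra) on a 4 cm^-1
    wavenumber grid.  ``noise_sigma`` is i.i.d. Gaussian noise per grid
    point, default 0 (clean maps).
    """

    bands: Tuple[BandSpec, ...]
    t_min: float = 250.0
    t_max: float = 340.0
    t_step: float = 10.0
    nu_min: float = 900.0
    nu_max: float = 1200.0
    nu_step: float = 4.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if not self.t_min < self.t_max:
            raise ValueError(f"t_min={self.t_min} must be < t_max={self.t_max}")
        if self.t_step <= 0:
            raise ValueError("t_step must be > 0")
        n_steps = (self.t_max - self.t_min) / self.t_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"(t_max - t_min) = {self.t_max - self.t_min} is not divisible "
                f"by t_step = {self.t_step}"
            )
        if self.nu_step <= 0:
            raise ValueError("nu_step must be > 0")
        if not self.nu_min < self.nu_max:
            raise ValueError(f"nu_min={self.nu_min} must be < nu_max={self.nu_max}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.t_step)) + 1
        return self.t_min + self.t_step * np.arange(n)

    @property
    def nu_grid(self) -> np.ndarray:
        n = int(np.floor((self.nu_max - self.nu_min) / self.nu_step + 1e-9)) + 1
        return self.nu_min + self.nu_step * np.arange(n)

    def to_dict(self) -> dict:
        return {
            "t_min": self.t_min,
            "t_max": self.t_max,
            "t_step": self.t_step,
            "nu_min": self.nu_min,
            "nu_max": self.nu_max,
            "nu_step": self.nu_step,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "bands": [
                {
                    "center": b.center,
                    "width": b.width,
                    "shape": b.shape,
                    "base_amplitude": b.base_amplitude,
                    "delta_amplitude": b.delta_amplitude,
                    "response": b.response,
                    "onset_T": b.onset_T,
                    "response_width": b.response_width,
                }
                for b in self.bands
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        bands = tuple(BandSpec(**b) for b in d.pop("bands"))
        return cls(bands=bands, **d)


@dataclass(frozen=True)
class GroundTruth:
    """True pairwise response ordering of the responding bands.

    ``ordering`` holds one tuple ``(center_a, center_b, relation)`` per
    unordered pair of responding bands, with relation ``"before"`` (band a
    responds at a lower onset temperature than band b) or ``"simultaneous"``
    (identical onset AND identical response shape).  A pair with equal
    onsets but different response shapes has no well-defined order and is
    omitted.
    """

    ordering: Tuple[Tuple[float, float, str], ...] = field(default_factory=tuple)

    def relation(self, center_a: float, center_b: float) -> str | None:
        """Relation of a to b; antisymmetric ('before' <-> 'after')."""
        for a, b, rel in self.ordering:
            if (a, b) == (center_a, center_b):
                return rel
            if (a, b) == (center_b, center_a):
                return {"before": "after", "after": "before"}.get(rel, rel)
        return None


def _effective_onset(band: BandSpec, t_min: float, t_max: float) -> float:
    # linear responses have no intrinsic onset; their midpoint sits at the
    # centre of the temperature range by symmetry
    if band.response == "linear":
        return 0.5 * (t_min + t_max)
    return band.onset_T


def _derive_truth(spec: SyntheticSpec) -> GroundTruth:
    responding = [b for b in spec.bands if b.responds]
    pairs: List[Tuple[float, float, str]] = []
    for i in range(len(responding)):
        for j in range(i + 1, len(responding)):
            a, b = responding[i], responding[j]
            oa = _effective_onset(a, spec.t_min, spec.t_max)
            ob = _effective_onset(b, spec.t_min, spec.t_max)
            if oa == ob:
                if a.response == b.response:
                    pairs.append((a.center, b.center, "simultaneous"))
                continue  # equal onsets, different shapes: no defined order
            if oa < ob:
                pairs.append((a.center, b.center, "before"))
            else:
                pairs.append((b.center, a.center, "before"))
    return GroundTruth(ordering=tuple(pairs))


def _lineshape(band: BandSpec, nu_grid: np.ndarray) -> np.ndarray:
    x = (np.asarray(nu_grid, dtype=float) - band.center) / band.width
    if band.shape == "gaussian":
        return np.exp(-np.log(2.0) * x * x)
    return 1.0 / (1.0 + x * x)  # lorentzian


def _amplitude(band: BandSpec, T: float, t_min: float, t_max: float) -> float:
    if band.response == "sigmoid":
        r = 1.0 / (1.0 + np.exp(-(T - band.onset_T) / band.response_width))
    else:  # linear ramp across the enclosing temperature range
        r = (T - t_min) / (t_max - t_min)
    return band.base_amplitude + band.delta_amplitude * r


def band_profile(
    band: BandSpec,
    nu_grid: np.ndarray,
    T: float,
    t_range: Tuple[float, float] = (250.0, 340.0),
) -> np.ndarray:
    """Evaluate one band at temperature T on a wavenumber grid.

    Returns ``amplitude(T) * lineshape(nu)`` where the line shape has unit
    height at the band centre and HWHM ``band.width``.  ``t_range`` is the
    (t_min, t_max) of the enclosing series; it only matters for the linear
    response, whose ramp is defined over that range.
    """
    return _amplitude(band, T, *t_range) * _lineshape(band, nu_grid)


def generate_series(spec: SyntheticSpec) -> Tuple[SpectralSeries, GroundTruth]:
    """Generate a temperature series plus its true response ordering.

    The intensity matrix is the superposition of all band profiles at each
    grid temperature, plus i.i.d. zero-mean Gaussian noise of standard
    deviation ``noise_sigma``.  The same spec (including seed) always yields
    a bit-identical series.  The ground truth is derived from the band
    parameters alone, never from the noisy matrix.
    """
    t_grid = spec.t_grid
    nu_grid = spec.nu_grid
    if spec.bands:
        narrowest = min(b.width for b in spec.bands)
        if spec.nu_step > narrowest:
            warnings.warn(
                f"wavenumber step {spec.nu_step} cm^-1 exceeds the narrowest band "
                f"width {narrowest} cm^-1; bands may be under-sampled",
                stacklevel=2,
            )
    I = np.zeros((t_grid.size, nu_grid.size))
    for band in spec.bands:
        profile = _lineshape(band, nu_grid)
        for ti, T in enumerate(t_grid):
            I[ti] += _amplitude(band, T, spec.t_min, spec.t_max) * profile
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        I = I + rng.normal(0.0, spec.noise_sigma, size=I.shape)
    series = SpectralSeries(
        nu=nu_grid, T=t_grid, I=I, meta={"generator": "noda2d.synthetic", "seed": spec.seed}
    )
    return series, _derive_truth(spec)
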