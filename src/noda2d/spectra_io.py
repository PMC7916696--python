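"""Read, write and preprocess perturbation-indexed spectral series.

The native interchange format is a wide CSV table: the first column holds
the wavenumber grid (cm^-1), every further column holds one spectrum, with
the column header giving the perturbation value (temperature in K) at which
it was acquired.  All operations in this module return a new, validated
:class:`SpectralSeries`; none mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralSeries",
    "read_series",
    "write_series",
    "select_region",
    "normalize",
    "baseline_correct",
    "resample_even",
    "DEFAULT_STANDARD_WINDOW",
]

#: Internal-standard normalization window (cm^-1) around the ~1055 cm^-1
#: cellulose-backbone C-OH band, which is insensitive to oxidation and can
#: therefore serve as a quantitative reference.
DEFAULT_STANDARD_WINDOW = (1045.0, 1065.0)

WAVENUMBER_LABEL = "wavenumber_cm-1"


@dataclass(frozen=True)
class SpectralSeries:
    """A k x n matrix of intensities I(nu, T) with its two axes.

    Parameters
    ----------
    nu : ndarray, shape (n,)
        Wavenumber grid in cm^-1, strictly increasing.  Instrument files
        often come wavenumber-descending; the constructor sorts both axes
        into the canonical ascending order (permuting ``I`` accordingly)
        so that all matrix code sees one orientation.
    T : ndarray, shape (k,)
        Perturbation values (temperature, K), strictly increasing after
        sorting.
    I : ndarray, shape (k, n)
        Intensities (absorbance, a.u.); row t is the spectrum at ``T[t]``.
    meta : dict
        Free-form provenance labels; never interpreted.
    """

    nu: np.ndarray
    T: np.ndarray
    I: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu, dtype=float).ravel()
        T = np.asarray(self.T, dtype=float).ravel()
        I = np.asarray(self.I, dtype=float)
        if I.ndim != 2:
            raise ValueError(f"I must be 2-D (k x n), got shape {I.shape}")
        k, n = I.shape
        if T.size != k or nu.size != n:
            raise ValueError(
                f"axis lengths do not match I: len(T)={T.size}, len(nu)={nu.size}, "
                f"I is {k}x{n}"
            )
        if k < 2:
            raise ValueError(f"need at least 2 spectra, got k={k}")
        if n < 2:
            raise ValueError(f"need at least 2 wavenumber points, got n={n}")
        if not (np.isfinite(nu).all() and np.isfinite(T).all() and np.isfinite(I).all()):
            raise ValueError("series contains NaN or infinite values")

        order_nu = np.argsort(nu, kind="stable")
        nu = nu[order_nu]
        I = I[:, order_nu]
        order_T = np.argsort(T, kind="stable")
        T = T[order_T]
        I = I[order_T, :]

        if np.any(np.diff(nu) <= 0):
            dup = nu[np.flatnonzero(np.diff(nu) <= 0)[0]]
            raise ValueError(f"duplicate wavenumber {dup!r} in grid")
        if np.any(np.diff(T) <= 0):
            dup = T[np.flatnonzero(np.diff(T) <= 0)[0]]
            raise ValueError(f"duplicate temperature {dup!r} in series")

        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "I", I)

    @property
    def k(self) -> int:
        """Number of spectra in the series."""
        return self.I.shape[0]

    @property
    def n(self) -> int:
        """Number of wavenumber grid points."""
        return self.I.shape[1]

    def spectrum(self, t_index: int) -> np.ndarray:
        return self.I[t_index]

    def equals(self, other: "SpectralSeries") -> bool:
        """Exact (bit-level) equality of the three arrays."""
        return (
            np.array_equal(self.nu, other.nu)
            and np.array_equal(self.T, other.T)
            and np.array_equal(self.I, other.I)
        )


def read_series(path) -> SpectralSeries:
    """Read a wide-CSV spectral series.

    The first column header is the wavenumber label; every remaining
    header must parse as a temperature.  Rows and columns may come in any
    order; the result is sorted ascending along both axes.

    Raises
    ------
    ValueError
        On ragged rows, non-numeric cells, or duplicated temperatures /
        wavenumbers, naming the offending row or column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw_header = fh.readline().rstrip("\n").rstrip("\r").split(",")
    if len(raw_header) < 3:
        raise ValueError(
            f"{path}: need a wavenumber column plus at least 2 temperature columns, "
            f"got {len(raw_header)} columns"
        )
    temps_list = []
    for col in raw_header[1:]:
        try:
            temps_list.append(float(col))
        except ValueError as exc:
            raise ValueError(
                f"{path}: column header {col!r} does not parse as a temperature"
            ) from exc
    temps = np.asarray(temps_list, dtype=float)
    seen: set = set()
    for t in temps_list:
        if t in seen:
            raise ValueError(f"{path}: duplicate temperature column {t!r}")
        seen.add(t)

    try:
        df = pd.read_csv(path, header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV (ragged rows?): {exc}") from exc

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at data row {r} "
            f"(column {df.columns[c]!r})"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at data row {r} (column {df.columns[c]!r})")

    nu = numeric.iloc[:, 0].to_numpy(dtype=float)
    uniq, counts = np.unique(nu, return_counts=True)
    if (counts > 1).any():
        raise ValueError(f"{path}: duplicated wavenumber row {uniq[counts > 1][0]!r}")

    I = numeric.iloc[:, 1:].to_numpy(dtype=float).T  # (k, n)
    return SpectralSeries(nu=nu, T=temps, I=I, meta={"source": str(path)})


def write_series(series: SpectralSeries, path) -> Path:
    """Write a series as wide CSV; ``read_series`` round-trips it exactly.

    Floats are emitted with :func:`repr`, whose shortest-exact decimal form
    makes the write -> read cycle an identity to full double precision and
    the byte stream deterministic for a given series.
    """
    path = Path(path)
    lines = [",".join([WAVENUMBER_LABEL] + [repr(float(t)) for t in series.T])]
    for j in range(series.n):
        row = [repr(float(series.nu[j]))] + [repr(float(v)) for v in series.I[:, j]]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def select_region(series: SpectralSeries, nu_lo: float, nu_hi: float) -> SpectralSeries:
    """Restrict to the closed wavenumber interval [nu_lo, nu_hi].

    Grid points are kept exactly (no resampling).  An interval containing
    fewer than 2 grid points is an error.
    """
    if not nu_lo < nu_hi:
        raise ValueError(f"invalid region: nu_lo={nu_lo} must be < nu_hi={nu_hi}")
    mask = (series.nu >= nu_lo) & (series.nu <= nu_hi)
    if mask.sum() < 2:
        raise ValueError(
            f"region [{nu_lo}, {nu_hi}] cm^-1 contains {int(mask.sum())} grid "
            f"point(s); need at least 2"
        )
    return SpectralSeries(
        nu=series.nu[mask], T=series.T, I=series.I[:, mask], meta=dict(series.meta)
    )


def normalize(
    series: SpectralSeries,
    mode: str = "band_area",
    band_window: Optional[Sequence[float]] = None,
) -> SpectralSeries:
    """Normalize each spectrum to account for the effective number of absorbers.

    Modes
    -----
    ``band_area``
        Divide each spectrum by the trapezoidal area of an internal-standard
        window (default 1045-1065 cm^-1, the oxidation-insensitive cellulose
        backbone band); after the call that window has unit area at every T.
    ``vector``
        Divide each spectrum by its Euclidean norm.
    ``none``
        Identity.
    """
    if mode == "none":
        return replace(series, meta=dict(series.meta))
    if mode == "vector":
        norms = np.linalg.norm(series.I, axis=1)
        if np.any(norms == 0):
            t = series.T[np.flatnonzero(norms == 0)[0]]
            raise ValueError(f"zero-norm spectrum at T={t} K cannot be vector-normalized")
        return replace(series, I=series.I / norms[:, None], meta=dict(series.meta))
    if mode == "band_area":
        lo, hi = band_window if band_window is not None else DEFAULT_STANDARD_WINDOW
        if lo < series.nu[0] or hi > series.nu[-1]:
            raise ValueError(
                f"standard window [{lo}, {hi}] cm^-1 lies outside the grid "
                f"[{series.nu[0]}, {series.nu[-1]}]"
            )
        mask = (series.nu >= lo) & (series.nu <= hi)
        if mask.sum() < 2:
            raise ValueError(f"standard window [{lo}, {hi}] cm^-1 has <2 grid points")
        areas = np.trapezoid(series.I[:, mask], series.nu[mask], axis=1)
        if np.any(areas == 0):
            t = series.T[np.flatnonzero(areas == 0)[0]]
            raise ValueError(f"zero standard-band area at T={t} K")
        return replace(series, I=series.I / areas[:, None], meta=dict(series.meta))
    raise ValueError(f"unknown normalization mode {mode!r}")


def baseline_correct(series: SpectralSeries, mode: str = "linear_endpoints") -> SpectralSeries:
    """Subtract, per spectrum, the straight line through its two end points.

    After correction both end points of every spectrum are exactly zero.
    A constant offset, being a degenerate line, is removed entirely.
    """
    if mode == "none":
        return replace(series, meta=dict(series.meta))
    if mode != "linear_endpoints":
        raise ValueError(f"unknown baseline mode {mode!r}")
    nu = series.nu
    frac = (nu - nu[0]) / (nu[-1] - nu[0])  # 0 at first point, 1 at last
    left = series.I[:, [0]]
    right = series.I[:, [-1]]
    line = left + (right - left) * frac[None, :]
    I = series.I - line
    # the endpoints are zero by construction up to rounding; pin them exactly
    I[:, 0] = 0.0
    I[:, -1] = 0.0
    return replace(series, I=I, meta=dict(series.meta))


def resample_even(series: SpectralSeries, axis: str = "temperature") -> SpectralSeries:
    """Interpolate onto a uniform temperature grid with the same endpoints and k.

    The correlation formulas assume equally spaced acquisitions along the
    perturbation; unevenly spaced series are therefore linearly interpolated
    channel by channel.  An already-uniform series is returned bit-identical.
    """
    if axis != "temperature":
        raise ValueError(f"unsupported resampling axis {axis!r}")
    if series.k < 3:
        raise ValueError("resampling needs at least 3 spectra")
    uniform = np.linspace(series.T[0], series.T[-1], series.k)
    if np.array_equal(uniform, series.T):
        return replace(series, meta=dict(series.meta))
    I = np.empty_like(series.I)
    for j in range(series.n):
        I[:, j] = np.interp(uniform, series.T, series.I[:, j])
    return replace(series, T=uniform, I=I, meta=dict(series.meta))
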