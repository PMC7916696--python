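"""Generalized 2D correlation spectroscopy core.

Given a series of k spectra I(nu, T) acquired along an increasing
perturbation trajectory (temperature here), the analysis proceeds in three
steps:

1.  **Dynamic spectra** — subtract a reference spectrum Ibar(nu) from every
    acquisition: Itilde(nu, T) = I(nu, T) - Ibar(nu).  The reference is, by
    convention, arbitrary; the first spectrum of the series is the default.

2.  **Synchronous map** — the covariance-like map of in-phase intensity
    changes,

        Theta(nu1, nu2) = 1/(k-1) * sum_i Itilde(nu1, T_i) * Itilde(nu2, T_i)

    Theta is symmetric; its diagonal (the auto-power spectrum) is >= 0.

3.  **Asynchronous map** — the out-of-phase map mediated by the discrete
    Hilbert transform across the perturbation index,

        Omega(nu1, nu2) = 1/(k-1) * sum_i Itilde(nu1, T_i)
                                       * sum_j M_ij * Itilde(nu2, T_j)

    where M is the Hilbert-Noda matrix, M_ij = 0 on the diagonal and
    1/(pi*(j-i)) elsewhere.  Omega is antisymmetric with an exactly zero
    diagonal; it vanishes identically for channels whose dynamic traces are
    proportional.

The discrete Noda matrix is used verbatim (no FFT-based continuous Hilbert
transform), so results follow the standard published computation route.
The 1/(k-1) normalization is applied once, outside both sums, as in the
canonical formulation; literature variants that normalize differently exist
and would rescale Omega by a constant without changing any sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .spectra_io import SpectralSeries

__all__ = [
    "DynamicSpectra",
    "CorrelationMaps",
    "hilbert_noda",
    "dynamic",
    "synchronous",
    "asynchronous",
    "correlate",
    "write_maps_csv",
    "read_map_csv",
    "save_maps",
    "load_maps",
]

ReferenceMode = Union[str, int]

#: warn (not fail) above this channel count: two dense n x n maps
_CHANNEL_GUARD = 5000


@dataclass(frozen=True)
class DynamicSpectra:
    """Reference-subtracted spectra Itilde(nu, T) and the reference used."""

    nu: np.ndarray
    T: np.ndarray
    Itilde: np.ndarray  # (k, n)
    reference: np.ndarray  # (n,)
    reference_mode: ReferenceMode

    @property
    def k(self) -> int:
        return self.Itilde.shape[0]

    @property
    def n(self) -> int:
        return self.Itilde.shape[1]


@dataclass(frozen=True)
class CorrelationMaps:
    """Synchronous/asynchronous maps with the Noda matrix that produced them.

    ``sync[i, j]`` is Theta(nu[i], nu[j]) and ``async_[i, j]`` is
    Omega(nu[i], nu[j]); the first index is nu1, the second nu2.
    """

    nu: np.ndarray
    sync: np.ndarray  # (n, n), symmetric
    async_: np.ndarray  # (n, n), antisymmetric, zero diagonal
    noda: np.ndarray  # (k, k)
    k: int

    @property
    def n(self) -> int:
        return self.nu.size

    def index_of(self, nu: float) -> int:
        """Index of the grid point nearest the requested wavenumber."""
        return int(np.argmin(np.abs(self.nu - nu)))


def hilbert_noda(k: int) -> np.ndarray:
    """The k x k Hilbert-Noda transformation matrix.

    M[i, i] = 0 and M[i, j] = 1/(pi*(j-i)) for i != j.  The matrix is
    exactly antisymmetric; applied across the perturbation index it
    implements the discrete Hilbert transform that phase-shifts each
    dynamic trace by 90 degrees.
    """
    if k < 2:
        raise ValueError(f"Hilbert-Noda matrix needs k >= 2, got k={k}")
    idx = np.arange(k)
    diff = idx[None, :] - idx[:, None]  # j - i
    with np.errstate(divide="ignore"):
        M = 1.0 / (np.pi * diff)
    np.fill_diagonal(M, 0.0)
    return M


def _resolve_reference(series: SpectralSeries, mode: ReferenceMode) -> np.ndarray:
    if isinstance(mode, (int, np.integer)) and not isinstance(mode, bool):
        return series.I[int(mode)].copy()
    if mode == "first":
        return series.I[0].copy()
    if mode == "last":
        return series.I[-1].copy()
    if mode == "mean":
        return series.I.mean(axis=0)
    if mode == "zero":
        return np.zeros(series.n)
    raise ValueError(
        f"unknown reference mode {mode!r}; expected 'first', 'last', 'mean', "
        f"'zero' or an integer spectrum index"
    )


def dynamic(series: SpectralSeries, reference_mode: ReferenceMode = "first") -> DynamicSpectra:
    """Subtract a reference spectrum from every spectrum in the series.

    Modes: ``first`` (default; the spectrum at T_min, so the first dynamic
    row is exactly zero), ``last``, ``mean`` (pointwise average over all k),
    ``zero`` (Itilde = I unchanged), or an integer index into the
    temperature-sorted series.
    """
    reference = _resolve_reference(series, reference_mode)
    return DynamicSpectra(
        nu=series.nu,
        T=series.T,
        Itilde=series.I - reference[None, :],
        reference=reference,
        reference_mode=reference_mode,
    )


def synchronous(dyn: DynamicSpectra) -> np.ndarray:
    """Synchronous correlation map Theta(nu1, nu2).

    Symmetrized after the matrix product so that float addition order can
    never leave a (sub-1e-12 relative) asymmetry in the result.
    """
    if dyn.k < 2:
        raise ValueError("synchronous map needs k >= 2 spectra")
    theta = dyn.Itilde.T @ dyn.Itilde / (dyn.k - 1)
    return (theta + theta.T) / 2.0


def asynchronous(dyn: DynamicSpectra, noda: np.ndarray | None = None) -> np.ndarray:
    """Asynchronous correlation map Omega(nu1, nu2).

    Antisymmetrized after the product and the diagonal pinned to exact
    zero, matching the algebraic identity x.T @ M @ x = 0 for
    antisymmetric M.  A k = 2 series is computed but flagged: the inner
    Hilbert-transform term is then degenerate and sequential inference
    from it is unreliable.
    """
    if dyn.k < 2:
        raise ValueError("asynchronous map needs k >= 2 spectra")
    if dyn.k == 2:
        warnings.warn(
            "asynchronous map with only k=2 spectra: the Hilbert-Noda inner term "
            "is degenerate and sequential-order inference is unreliable",
            stacklevel=2,
        )
    M = hilbert_noda(dyn.k) if noda is None else noda
    omega = dyn.Itilde.T @ (M @ dyn.Itilde) / (dyn.k - 1)
    omega = (omega - omega.T) / 2.0
    np.fill_diagonal(omega, 0.0)
    return omega


def correlate(
    series: SpectralSeries, reference_mode: ReferenceMode = "first"
) -> CorrelationMaps:
    """Convenience composition: dynamic spectra -> both correlation maps."""
    if series.n > _CHANNEL_GUARD:
        warnings.warn(
            f"{series.n} wavenumber channels -> two dense {series.n}x{series.n} maps; "
            f"consider select_region() first",
            stacklevel=2,
        )
    dyn = dynamic(series, reference_mode)
    M = hilbert_noda(dyn.k)
    return CorrelationMaps(
        nu=series.nu,
        sync=synchronous(dyn),
        async_=asynchronous(dyn, noda=M),
        noda=M,
        k=dyn.k,
    )


# ---------------------------------------------------------------------------
# serialization


def _write_map(nu: np.ndarray, mat: np.ndarray, path) -> None:
    # repr() floats: exact round-trip, deterministic bytes
    lines = [",".join(["nu1_cm-1"] + [repr(float(v)) for v in nu])]
    for i in range(nu.size):
        lines.append(",".join([repr(float(nu[i]))] + [repr(float(v)) for v in mat[i]]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_maps_csv(maps: CorrelationMaps, sync_path, async_path) -> None:
    """Write both maps as labelled CSV matrices (first row/column = nu)."""
    _write_map(maps.nu, maps.sync, sync_path)
    _write_map(maps.nu, maps.async_, async_path)


def read_map_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read one labelled map CSV back; returns (nu, matrix)."""
    df = pd.read_csv(path, float_precision="round_trip")
    nu = df.iloc[:, 0].to_numpy(dtype=float)
    return nu, df.iloc[:, 1:].to_numpy(dtype=float)


def save_maps(maps: CorrelationMaps, path) -> Path:
    """Save a CorrelationMaps bundle to one compressed binary container."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez_compressed(
        path, nu=maps.nu, sync=maps.sync, async_=maps.async_, noda=maps.noda, k=maps.k
    )
    return path


def load_maps(path) -> CorrelationMaps:
    with np.load(path) as z:
        return CorrelationMaps(
            nu=z["nu"], sync=z["sync"], async_=z["async_"], noda=z["noda"], k=int(z["k"])
        )
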