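"""Contour plots of correlation maps (convenience surface only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .corr2d import CorrelationMaps

__all__ = ["plot_map"]


def plot_map(maps: CorrelationMaps, which: str = "sync", path=None, n_levels: int = 21):
    """Filled-contour plot of one map with the diagonal drawn.

    Positive and negative regions use a diverging colormap centred on zero
    so both signs stay distinguishable.  Returns the output path (when
    given) or the matplotlib figure.
    """
    if which == "sync":
        mat, title = maps.sync, "Synchronous map Θ(ν1, ν2)"
    elif which == "async":
        mat, title = maps.async_, "Asynchronous map Ω(ν1, ν2)"
    else:
        raise ValueError(f"unknown map {which!r}")

    top = np.abs(mat).max()
    if top == 0:
        top = 1.0
    levels = np.linspace(-top, top, n_levels)
    fig, ax = plt.subplots(figsize=(6, 5))
    # mat[i, j] = map(nu1=nu[i], nu2=nu[j]): nu1 on x, nu2 on y
    cf = ax.contourf(maps.nu, maps.nu, mat.T, levels=levels, cmap="RdBu_r")
    ax.plot(maps.nu, maps.nu, color="k", lw=0.8)
    ax.set_xlabel(r"$\nu_1$ (cm$^{-1}$)")
    ax.set_ylabel(r"$\nu_2$ (cm$^{-1}$)")
    ax.set_title(title)
    fig.colorbar(cf, ax=ax, label="correlation intensity (a.u.$^2$)")
    fig.tight_layout()
    if path is not None:
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    return fig
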