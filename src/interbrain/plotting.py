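"""Quick-look figures: coherence maps and the cohort coherence spectrum."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_coherence_map", "plot_spectrum"]


def plot_coherence_map(cmap, path=None, title="wavelet coherence"):
    """Heat map of r2 over time and frequency with the COI boundary."""
    fig, ax = plt.subplots(figsize=(8, 4))
    freqs_mhz = cmap.frequencies * 1000.0
    n = cmap.r2.shape[1]
    t = np.arange(n) * cmap.grid.dt
    im = ax.pcolormesh(t, freqs_mhz, cmap.r2, vmin=0, vmax=1, shading="auto")
    from .wavelet import fourier_factor

    edge = np.maximum(np.minimum(t, t[-1] - t), 1e-9)
    coi_scale = edge / np.sqrt(2.0)  # largest in-COI scale at each time
    coi_f = 1000.0 / (fourier_factor(cmap.grid.omega0) * coi_scale)
    ax.plot(t, np.clip(coi_f, freqs_mhz.min(), freqs_mhz.max()), "w--", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (mHz)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=r"$R^2$")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_spectrum(spectrum, band=None, path=None):
    """ROI-by-frequency coherence heat map with the grand-mean curve."""
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(7, 5), sharex=True, height_ratios=[3, 1]
    )
    mhz = spectrum.frequencies * 1000.0
    ax0.pcolormesh(
        mhz, np.arange(spectrum.roi_by_scale.shape[0]), spectrum.roi_by_scale,
        shading="auto",
    )
    ax0.set_ylabel("ROI")
    ax1.plot(mhz, spectrum.mean_curve, "r-")
    if band is not None:
        for f in band[:2]:
            ax1.axvline(1000.0 * f, color="k", ls=":")
    ax1.set_xlabel("frequency (mHz)")
    ax1.set_ylabel(r"mean $R^2$")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
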