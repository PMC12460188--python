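"""Empirical frequency-band selection from the cohort coherence spectrum.

The spectrum averages magnitude-squared coherence over dyads and all
in-block time points, per ROI and scale.  Averaging once more over ROIs
yields a single mean curve over the log-spaced scales; after trimming the
artifact-prone extremes (below 9.6 mHz and above 220 mHz by default) the
band of interest is read off the curve's slope extrema: the peak frequency
at the maximum, the high edge at the steepest rise on the high-frequency
side and the low edge at the steepest fall on the low-frequency side.
Slopes are taken on the scale index, i.e. per voice of the geometric grid,
which is equivalent to d/d(log f).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import NoBandError
from .wavelet import ScaleGrid

__all__ = [
    "CoherenceSpectrum",
    "mean_coherence_spectrum",
    "trim_spectrum",
    "select_band",
]


@dataclass(frozen=True)
class CoherenceSpectrum:
    """Per-ROI mean coherence against frequency, plus the grand-mean curve.

    ``frequencies`` are in Hz, descending (grid order); ``roi_by_scale`` has
    one row per ROI.  ``roi_labels`` keeps the ROI identity through trimming
    and exclusion.
    """

    frequencies: np.ndarray
    roi_by_scale: np.ndarray
    roi_labels: tuple[int, ...]
    trim_bounds: tuple[float, float] | None = None

    @property
    def mean_curve(self) -> np.ndarray:
        return self.roi_by_scale.mean(axis=0)


def mean_coherence_spectrum(maps: dict, windows: dict) -> CoherenceSpectrum:
    """Average coherence maps over dyads and in-window time points.

    ``maps`` maps (dyad_id, roi) to a CoherenceMap (or bare r2 array);
    ``windows`` maps dyad_id to a sequence of objects with ``start_index``
    and ``end_index`` (or plain (start, end) tuples).  All maps must share
    one grid.
    """
    if not maps:
        raise ValueError("no coherence maps supplied")
    rois = sorted({roi for (_, roi) in maps})
    freqs = None
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for (dyad, roi), cmap in maps.items():
        r2 = getattr(cmap, "r2", cmap)
        if freqs is None:
            freqs = getattr(cmap, "frequencies", None)
            if freqs is None:
                raise ValueError("maps must expose frequencies")
        wins = windows[dyad]
        if len(wins) == 0:
            raise ValueError(f"empty window set for dyad {dyad}")
        for w in wins:
            s, e = (
                (w.start_index, w.end_index)
                if hasattr(w, "start_index")
                else (w[0], w[1])
            )
            sums[roi] = sums.get(roi, 0) + r2[:, s:e].sum(axis=1)
            counts[roi] = counts.get(roi, 0) + (e - s)
    roi_by_scale = np.vstack([sums[r] / counts[r] for r in rois])
    return CoherenceSpectrum(
        frequencies=np.asarray(freqs),
        roi_by_scale=roi_by_scale,
        roi_labels=tuple(rois),
    )


def trim_spectrum(
    spectrum: CoherenceSpectrum, low: float = 0.0096, high: float = 0.220
) -> CoherenceSpectrum:
    """Drop scales outside [low, high] Hz; idempotent for fixed bounds."""
    if not low < high:
        raise ValueError("low must be below high")
    keep = (spectrum.frequencies >= low) & (spectrum.frequencies <= high)
    if not keep.any():
        raise ValueError("trim bounds remove every scale")
    return replace(
        spectrum,
        frequencies=spectrum.frequencies[keep],
        roi_by_scale=spectrum.roi_by_scale[:, keep],
        trim_bounds=(low, high),
    )


def select_band(
    spectrum: CoherenceSpectrum, smooth_width: int = 0
) -> tuple[float, float, float]:
    """Select (f_low, f_high, f_peak) from the mean curve's slope extrema.

    The curve is indexed high-frequency first.  The peak must be a strict
    interior maximum; the high edge is the index of the steepest positive
    slope before the peak, the low edge the steepest negative slope after
    it (central differences; one-sided at the ends; slope ties resolved
    toward the scale farthest from the peak).  Optional light smoothing
    (centred moving average of ``smooth_width``) is off by default.
    """
    curve = np.asarray(spectrum.mean_curve, dtype=float)
    freqs = spectrum.frequencies
    if smooth_width and smooth_width > 1:
        k = np.ones(smooth_width) / smooth_width
        pad = smooth_width // 2
        ext = np.r_[np.repeat(curve[0], pad), curve, np.repeat(curve[-1], pad)]
        curve = np.convolve(ext, k, mode="same")[pad : pad + freqs.size]
    n = curve.size
    if n < 3:
        raise NoBandError("need at least 3 scales to select a band")
    peak = int(np.argmax(curve))
    if peak in (0, n - 1) or not (
        curve[peak] > curve[peak - 1] and curve[peak] > curve[peak + 1]
    ):
        raise NoBandError("mean coherence curve has no strict interior peak")
    slope = np.gradient(curve)
    left = slope[:peak]  # high-frequency side: rising toward the peak
    right = slope[peak + 1 :]  # low-frequency side: falling away from it
    if left.size == 0 or right.size == 0 or left.max() <= 0 or right.min() >= 0:
        raise NoBandError("no slope extremum on one side of the peak")
    tol = 1e-9 * max(np.abs(slope).max(), 1e-30)
    hi_idx = int(np.flatnonzero(left >= left.max() - tol)[0])
    lo_idx = peak + 1 + int(np.flatnonzero(right <= right.min() + tol)[-1])
    return float(freqs[lo_idx]), float(freqs[hi_idx]), float(freqs[peak])
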