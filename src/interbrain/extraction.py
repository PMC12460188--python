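"""From coherence maps and event tables to one term per dyad x condition x ROI.

Block windows start at the first trial onset plus a hemodynamic-delay
exclusion (default 5 s) and end at the offset of the last trial's feedback;
indices are half-open with ceil/floor rounding so no sample outside the
block contributes.  Per-block coherence terms are the mean of r2 over the
band's scales and the window's time points (cone-of-influence points are
included by default).  Terms are averaged over runs, and the solo and watch
blocks are merged into a single "solo" condition, leaving four conditions
per dyad.  ROIs with unusable data in more than a third of dyads are
excluded from the analysis entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyWindowError

__all__ = [
    "ANALYSIS_CONDITIONS",
    "BlockWindow",
    "block_windows",
    "extract_term",
    "aggregate_table",
    "exclude_rois",
]

#: The four conditions entering group statistics (solo/watch merged).
ANALYSIS_CONDITIONS = ("cooperation", "communication", "competition", "solo")


@dataclass(frozen=True)
class BlockWindow:
    """Half-open extraction window [start_index, end_index) for one block."""

    condition: str
    run: int
    block: int
    start: float
    end: float
    start_index: int
    end_index: int


def block_windows(
    events: pd.DataFrame,
    tr: float,
    hemo_exclusion: float = 5.0,
    run: int = 0,
    offset_event: str = "feedback",
) -> tuple[list[BlockWindow], list[str]]:
    """Extraction windows per block, with a report of degenerate blocks.

    ``offset_event`` selects what counts as the last trial's offset: the end
    of its feedback presentation (default) or of its stimulus/response slot.
    Blocks shorter than the hemodynamic exclusion are reported, not fatal.
    """
    trials = events[events["event"] != "block"]
    if trials.empty:
        raise ValueError("event table contains no trial-level rows")
    windows: list[BlockWindow] = []
    problems: list[str] = []
    for block, grp in trials.groupby("block", sort=True):
        cond = grp["trial_type"].iloc[0]
        first_onset = grp["onset"].min()
        off = grp[grp["event"] == offset_event]
        if off.empty:
            off = grp
        last_offset = (off["onset"] + off["duration"]).max()
        start = first_onset + hemo_exclusion
        end = last_offset
        s_idx = int(np.ceil(start / tr))
        e_idx = int(np.floor(end / tr))
        if start >= end or s_idx >= e_idx:
            problems.append(
                f"block {block} ({cond}): empty window after {hemo_exclusion:.1f} s exclusion"
            )
            continue
        windows.append(
            BlockWindow(
                condition=cond,
                run=run,
                block=int(block),
                start=float(start),
                end=float(end),
                start_index=s_idx,
                end_index=e_idx,
            )
        )
    return windows, problems


def extract_term(
    cmap,
    window: BlockWindow,
    band: tuple[float, float],
    use_coi_mask: bool = False,
) -> float:
    """Mean r2 over the band's scales and the window's time points."""
    r2 = getattr(cmap, "r2", cmap)
    grid = getattr(cmap, "grid", None)
    if grid is None:
        raise ValueError("extract_term needs a CoherenceMap with a grid")
    idx = grid.band_indices(band[0], band[1])
    if idx.size == 0:
        raise ValueError(f"no scales inside band {band}")
    sl = slice(window.start_index, window.end_index)
    if window.start_index >= window.end_index:
        raise EmptyWindowError(f"window {window} is empty")
    block = r2[idx, sl]
    if use_coi_mask:
        mask = cmap.coi_mask[idx, sl]
        if not mask.any():
            raise EmptyWindowError("no in-COI samples in window")
        return float(block[mask].mean())
    return float(block.mean())


def aggregate_table(block_terms: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-block terms into the raw dyad x condition x ROI table.

    Input columns: dyad, run, block, condition, roi, value.  Watch blocks
    are folded into the solo condition, and the value is the grand mean over
    all contributing block terms (runs included).  Cells missing in every
    run are kept with a set missing mask.
    """
    df = block_terms.copy()
    df["condition"] = df["condition"].replace({"watch": "solo"})
    df = df[df["condition"].isin(ANALYSIS_CONDITIONS)]
    agg = (
        df.groupby(["dyad", "condition", "roi"], sort=True)["value"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "value", "count": "n_blocks"})
    )
    full = pd.MultiIndex.from_product(
        [
            sorted(df["dyad"].unique()),
            ANALYSIS_CONDITIONS,
            sorted(df["roi"].unique()),
        ],
        names=["dyad", "condition", "roi"],
    )
    agg = (
        agg.set_index(["dyad", "condition", "roi"])
        .reindex(full)
        .reset_index()
    )
    agg["n_blocks"] = agg["n_blocks"].fillna(0).astype(int)
    agg["missing"] = agg["value"].isna()
    agg["stage"] = "raw"
    return agg


def exclude_rois(
    roi_missing: np.ndarray,
    threshold: float = 1.0 / 3.0,
    dyad_threshold: float = 1.0 / 3.0,
) -> np.ndarray:
    """Boolean keep-mask over ROIs from per-dyad missing-data fractions.

    ``roi_missing`` is (n_dyads, n_rois); a dyad is unusable for an ROI when
    its missing fraction exceeds ``dyad_threshold``, and the ROI is dropped
    when the proportion of unusable dyads exceeds ``threshold`` (strictly).
    """
    frac = np.asarray(roi_missing, dtype=float)
    if frac.ndim != 2:
        raise ValueError("roi_missing must be (n_dyads, n_rois)")
    if (frac < 0).any() or (frac > 1).any():
        raise ValueError("missing fractions must lie in [0, 1]")
    unusable = frac > dyad_threshold
    return unusable.mean(axis=0) <= threshold
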