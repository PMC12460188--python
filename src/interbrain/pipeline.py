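"""End-to-end orchestration: simulate -> WTC -> band -> terms -> baseline -> stats.

The pipeline is checkpointed: every stage can run in memory
(:func:`analyze_cohort`) or against a run directory whose artifacts the
previous stage wrote (the ``stage_*`` functions used by the CLI).  Heavy
computation is organised so that per-block coherence is reduced to
per-scale means while maps are still in memory: nothing larger than a
(blocks x scales) summary is ever retained per dyad and ROI, which keeps
cohorts of tens of dyads and hundreds of surrogate pairings inside desk-top
memory.  Surrogate coherence is evaluated only on the selected band's scale
rows (plus the scale-smoothing margin), which gives values identical to a
full-grid computation at a fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import platform
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .band import CoherenceSpectrum, select_band, trim_spectrum
from .baseline import (
    SurrogatePlan,
    compute_baseline,
    make_surrogate_plan,
    subtract_baseline,
)
from .exceptions import ConfigError
from .extraction import (
    BlockWindow,
    aggregate_table,
    block_windows,
    exclude_rois,
)
from .io import (
    read_events,
    read_series_hdf5,
    read_table,
    write_config,
    write_events,
    write_series_hdf5,
    write_table,
)
from .simulate import DyadRecord, SimulationConfig, manifest_from_dyads, simulate_cohort
from .stats import run_group_stats
from .wavelet import ScaleGrid, WtcEngine, build_scale_grid

__all__ = [
    "AnalysisConfig",
    "PipelineConfig",
    "AnalysisResult",
    "analyze_cohort",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters; defaults follow the reference protocol."""

    f_min: float = 0.0039
    f_max: float = 0.2894
    voices: int = 12
    n_scales_smooth: int = 12
    trim_low: float = 0.0096
    trim_high: float = 0.220
    hemo_exclusion: float = 5.0
    n_permutations: int | None = None
    fdr_q: float = 0.05
    band_override: tuple[float, float] | None = None
    baseline_strategy: str = "mean"
    use_coi_mask: bool = False
    roi_exclusion_threshold: float = 1.0 / 3.0
    curve_smooth: int = 0
    sqrt_before_z: bool = False
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


@dataclass
class AnalysisResult:
    grid: ScaleGrid
    kept_rois: list[int]
    spectrum: CoherenceSpectrum
    band: tuple[float, float, float]
    block_terms: pd.DataFrame
    raw_table: pd.DataFrame
    surrogate_plan: SurrogatePlan
    surrogate_terms: pd.DataFrame
    baseline_table: pd.DataFrame
    corrected_table: pd.DataFrame
    omnibus: pd.DataFrame
    posthoc: pd.DataFrame
    outlier_log: pd.DataFrame
    window_problems: list[str]


# --------------------------------------------------------------------------
# shared helpers


def _windows_by_dyad(
    dyads: list[DyadRecord],
    events: dict[tuple[str, int], pd.DataFrame],
    analysis: AnalysisConfig,
) -> tuple[dict[str, dict[int, list[BlockWindow]]], list[str]]:
    out: dict[str, dict[int, list[BlockWindow]]] = {}
    problems: list[str] = []
    for d in dyads:
        out[d.dyad_id] = {}
        for r in range(d.series_a.shape[0]):
            wins, probs = block_windows(
                events[(d.dyad_id, r)],
                tr=d.tr,
                hemo_exclusion=analysis.hemo_exclusion,
                run=r,
            )
            out[d.dyad_id][r] = wins
            problems += [f"{d.dyad_id} run {r}: {p}" for p in probs]
    return out, problems


def _kept_rois(dyads: list[DyadRecord], analysis: AnalysisConfig) -> list[int]:
    miss = np.stack(
        [np.maximum(d.roi_missing_a, d.roi_missing_b) for d in dyads]
    )
    keep = exclude_rois(miss, threshold=analysis.roi_exclusion_threshold)
    return [int(i) for i in np.flatnonzero(keep)]


def _grid_for(dyads: list[DyadRecord], analysis: AnalysisConfig) -> ScaleGrid:
    return build_scale_grid(
        analysis.f_min, analysis.f_max, analysis.voices, dt=dyads[0].tr
    )


def _coi_weights(engine: WtcEngine, grid: ScaleGrid, n: int, use_coi: bool):
    if not use_coi:
        return None
    from .wavelet import cone_of_influence

    r0, r1 = engine.rows
    return cone_of_influence(grid, n)[r0:r1]


def _window_mean(
    r2: np.ndarray, w: BlockWindow, coi: np.ndarray | None
) -> np.ndarray:
    """Per-scale mean of r2 over a window (optionally COI-masked)."""
    seg = r2[:, w.start_index : w.end_index]
    if coi is None:
        return seg.mean(axis=1)
    m = coi[:, w.start_index : w.end_index]
    cnt = np.maximum(m.sum(axis=1), 1)
    return (seg * m).sum(axis=1) / cnt


# --------------------------------------------------------------------------
# stage 1: real-dyad coherence -> per-block per-scale means + spectrum


def compute_real_coherence(
    dyads: list[DyadRecord],
    events: dict[tuple[str, int], pd.DataFrame],
    analysis: AnalysisConfig,
    kept_rois: list[int] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, CoherenceSpectrum, list[str]]:
    """WTC per dyad x ROI x run, reduced to per-block per-scale means.

    Returns (index, values, spectrum, window_problems): ``values`` holds one
    row of per-scale means per (dyad, run, block, roi) record in ``index``.
    """
    if kept_rois is None:
        kept_rois = _kept_rois(dyads, analysis)
    grid = _grid_for(dyads, analysis)
    n_vol = dyads[0].series_a.shape[1]
    engine = WtcEngine(grid, n_vol, analysis.n_scales_smooth)
    coi = _coi_weights(engine, grid, n_vol, analysis.use_coi_mask)
    windows, problems = _windows_by_dyad(dyads, events, analysis)

    rows = []
    vecs = []
    ns = len(grid)
    spec_sum = {roi: np.zeros(ns) for roi in kept_rois}
    spec_cnt = {roi: 0 for roi in kept_rois}
    for d in dyads:
        for r in range(d.series_a.shape[0]):
            wins = windows[d.dyad_id][r]
            for roi in kept_rois:
                wa = engine.transform(d.series_a[r, :, roi])
                wb = engine.transform(d.series_b[r, :, roi])
                pa = engine.smoothed_power(wa)
                pb = engine.smoothed_power(wb)
                r2, _ = engine.coherence(wa, pa, wb, pb)
                for w in wins:
                    vec = _window_mean(r2, w, coi)
                    rows.append(
                        {
                            "dyad": d.dyad_id,
                            "run": r,
                            "block": w.block,
                            "condition": w.condition,
                            "roi": roi,
                        }
                    )
                    vecs.append(vec)
                    spec_sum[roi] += r2[:, w.start_index : w.end_index].sum(axis=1)
                    spec_cnt[roi] += w.end_index - w.start_index
    index = pd.DataFrame(rows, columns=["dyad", "run", "block", "condition", "roi"])
    values = np.vstack(vecs)
    spectrum = CoherenceSpectrum(
        frequencies=grid.frequencies.copy(),
        roi_by_scale=np.vstack([spec_sum[r] / max(spec_cnt[r], 1) for r in kept_rois]),
        roi_labels=tuple(kept_rois),
    )
    return index, values, spectrum, problems


def band_from_spectrum(
    spectrum: CoherenceSpectrum, analysis: AnalysisConfig
) -> tuple[float, float, float]:
    """Selected (f_low, f_high, f_peak); honours the band override."""
    if analysis.band_override is not None:
        f1, f2 = analysis.band_override
        return float(f1), float(f2), float(np.sqrt(f1 * f2))
    trimmed = trim_spectrum(spectrum, analysis.trim_low, analysis.trim_high)
    return select_band(trimmed, smooth_width=analysis.curve_smooth)


def terms_from_blockmeans(
    index: pd.DataFrame,
    values: np.ndarray,
    grid: ScaleGrid,
    band: tuple[float, float],
) -> pd.DataFrame:
    """Scalar per-block terms: mean of the per-scale means over band scales."""
    idx = grid.band_indices(band[0], band[1])
    if idx.size == 0:
        raise ConfigError(f"no grid scales inside band {band}")
    out = index.copy()
    out["value"] = values[:, idx].mean(axis=1)
    return out


# --------------------------------------------------------------------------
# stage 2: surrogate pairs on the band rows only


def compute_surrogate_terms(
    dyads: list[DyadRecord],
    events: dict[tuple[str, int], pd.DataFrame],
    analysis: AnalysisConfig,
    band: tuple[float, float],
    plan: SurrogatePlan,
    kept_rois: list[int] | None = None,
) -> pd.DataFrame:
    """Extracted coherence terms for every planned surrogate pairing.

    Windows of the two (unacquainted) subjects are intersected per block;
    with a shared task schedule they coincide.  Returns one row per
    (subject, partner, condition, roi) after run/block aggregation, listing
    each unordered pairing in both directions.
    """
    if kept_rois is None:
        kept_rois = _kept_rois(dyads, analysis)
    grid = _grid_for(dyads, analysis)
    idx = grid.band_indices(band[0], band[1])
    if idx.size == 0:
        raise ConfigError(f"no grid scales inside band {band}")
    rows_range = (int(idx.min()), int(idx.max()) + 1)
    n_vol = dyads[0].series_a.shape[1]
    engine = WtcEngine(grid, n_vol, analysis.n_scales_smooth, rows=rows_range)
    coi = _coi_weights(engine, grid, n_vol, analysis.use_coi_mask)
    windows, _ = _windows_by_dyad(dyads, events, analysis)

    side: dict[str, tuple[int, str]] = {}
    for i, d in enumerate(dyads):
        side[d.subject_a_id] = (i, "a")
        side[d.subject_b_id] = (i, "b")

    pairs: set[tuple[str, str]] = set()
    for subj, partners in plan.partners.items():
        for p in partners:
            pair = (subj, p) if side[subj][1] == "a" else (p, subj)
            pairs.add(pair)

    def series_of(subj: str, run: int, roi: int) -> np.ndarray:
        i, s = side[subj]
        arr = dyads[i].series_a if s == "a" else dyads[i].series_b
        return arr[run, :, roi]

    n_runs = dyads[0].series_a.shape[0]
    recs = []
    for roi in kept_rois:
        for r in range(n_runs):
            cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

            def get(subj: str):
                hit = cache.get(subj)
                if hit is None:
                    w = engine.transform(series_of(subj, r, roi))
                    hit = cache[subj] = (w, engine.smoothed_power(w))
                return hit

            for sa, sb in sorted(pairs):
                wa, pa = get(sa)
                wb, pb = get(sb)
                r2, _ = engine.coherence(wa, pa, wb, pb)
                wins_a = {w.block: w for w in windows[dyads[side[sa][0]].dyad_id][r]}
                wins_b = {w.block: w for w in windows[dyads[side[sb][0]].dyad_id][r]}
                for b in sorted(set(wins_a) & set(wins_b)):
                    w1, w2 = wins_a[b], wins_b[b]
                    if w1.condition != w2.condition:
                        continue
                    s_idx = max(w1.start_index, w2.start_index)
                    e_idx = min(w1.end_index, w2.end_index)
                    if s_idx >= e_idx:
                        continue
                    inter = BlockWindow(
                        w1.condition, r, b, max(w1.start, w2.start),
                        min(w1.end, w2.end), s_idx, e_idx,
                    )
                    recs.append(
                        {
                            "dyad": f"{sa}|{sb}",
                            "run": r,
                            "block": b,
                            "condition": inter.condition,
                            "roi": roi,
                            "value": float(_window_mean(r2, inter, coi).mean()),
                        }
                    )
    pair_blocks = pd.DataFrame(
        recs, columns=["dyad", "run", "block", "condition", "roi", "value"]
    )
    agg = aggregate_table(pair_blocks)
    agg = agg[~agg["missing"]]
    split = agg["dyad"].str.split("|", expand=True)
    fwd = agg.assign(subject=split[0], partner=split[1])
    rev = agg.assign(subject=split[1], partner=split[0])
    return pd.concat([fwd, rev], ignore_index=True)[
        ["subject", "partner", "condition", "roi", "value"]
    ]


# --------------------------------------------------------------------------
# full in-memory analysis


def analyze_cohort(
    dyads: list[DyadRecord],
    events: dict[tuple[str, int], pd.DataFrame],
    analysis: AnalysisConfig | None = None,
) -> AnalysisResult:
    """Run the complete analysis on an in-memory cohort."""
    if analysis is None:
        analysis = AnalysisConfig()
    kept = _kept_rois(dyads, analysis)
    if not kept:
        raise ConfigError("every ROI was excluded by the missing-data rule")
    grid = _grid_for(dyads, analysis)
    index, values, spectrum, problems = compute_real_coherence(
        dyads, events, analysis, kept
    )
    band3 = band_from_spectrum(spectrum, analysis)
    band = (band3[0], band3[1])
    block_terms = terms_from_blockmeans(index, values, grid, band)
    raw = aggregate_table(block_terms)

    manifest = manifest_from_dyads(dyads)
    plan = make_surrogate_plan(
        manifest, analysis.n_permutations, seed=analysis.seed
    )
    surrogate_terms = compute_surrogate_terms(
        dyads, events, analysis, band, plan, kept
    )
    baseline_table = compute_baseline(plan, surrogate_terms)
    corrected = subtract_baseline(
        raw, baseline_table, manifest, strategy=analysis.baseline_strategy
    )
    stats = run_group_stats(
        corrected, fdr_q=analysis.fdr_q, sqrt_before_z=analysis.sqrt_before_z
    )
    return AnalysisResult(
        grid=grid,
        kept_rois=kept,
        spectrum=spectrum,
        band=band3,
        block_terms=block_terms,
        raw_table=raw,
        surrogate_plan=plan,
        surrogate_terms=surrogate_terms,
        baseline_table=baseline_table,
        corrected_table=corrected,
        omnibus=stats["omnibus"],
        posthoc=stats["posthoc"],
        outlier_log=stats["outlier_log"],
        window_problems=problems,
    )


# --------------------------------------------------------------------------
# run-directory stages (checkpointed pipeline used by the CLI)


def stage_simulate(config: SimulationConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dyads, events, truth = simulate_cohort(config)
    write_series_hdf5(dyads, out / "series.h5")
    for (dyad, r), ev in events.items():
        write_events(ev, out / f"events_{dyad}_run-{r}.tsv")
    write_table(manifest_from_dyads(dyads), out / "manifest.tsv")
    miss_rows = []
    for d in dyads:
        for subj, frac in (
            (d.subject_a_id, d.roi_missing_a),
            (d.subject_b_id, d.roi_missing_b),
        ):
            for roi, f in enumerate(frac):
                miss_rows.append({"subject": subj, "roi": roi, "fraction": f})
    write_table(pd.DataFrame(miss_rows), out / "roi_missing.tsv")
    write_table(truth, out / "ground_truth.tsv")
    write_config(config, out / "simulation.yaml")
    return out


def load_cohort(
    run_dir: str | Path,
) -> tuple[list[DyadRecord], dict[tuple[str, int], pd.DataFrame]]:
    """Rebuild the in-memory cohort from a run directory's artifacts."""
    run_dir = Path(run_dir)
    subjects = read_series_hdf5(run_dir / "series.h5")
    manifest = read_table(run_dir / "manifest.tsv")
    miss_path = run_dir / "roi_missing.tsv"
    missing: dict[str, np.ndarray] = {}
    if miss_path.exists():
        mdf = read_table(miss_path)
        for subj, grp in mdf.groupby("subject"):
            missing[subj] = grp.sort_values("roi")["fraction"].to_numpy(float)
    dyads = []
    events: dict[tuple[str, int], pd.DataFrame] = {}
    for _, row in manifest.iterrows():
        sa, sb = subjects[row["subject_a"]], subjects[row["subject_b"]]
        dyads.append(
            DyadRecord(
                dyad_id=row["dyad"],
                subject_a_id=row["subject_a"],
                subject_b_id=row["subject_b"],
                scanner_of_a=row["scanner_a"],
                scanner_of_b=row["scanner_b"],
                tr=sa["tr"],
                series_a=sa["series"],
                series_b=sb["series"],
                roi_missing_a=missing.get(
                    row["subject_a"], np.zeros(sa["series"].shape[2])
                ),
                roi_missing_b=missing.get(
                    row["subject_b"], np.zeros(sb["series"].shape[2])
                ),
            )
        )
        for r in range(sa["series"].shape[0]):
            events[(row["dyad"], r)] = read_events(
                run_dir / f"events_{row['dyad']}_run-{r}.tsv"
            )
    return dyads, events


def _mhz(f: float) -> float:
    return 1000.0 * f


def stage_wtc(run_dir: str | Path, analysis: AnalysisConfig) -> None:
    run_dir = Path(run_dir)
    dyads, events = load_cohort(run_dir)
    kept = _kept_rois(dyads, analysis)
    grid = _grid_for(dyads, analysis)
    index, values, spectrum, problems = compute_real_coherence(
        dyads, events, analysis, kept
    )
    with h5py.File(run_dir / "blockmeans.h5", "w") as h5:
        h5.create_dataset("values", data=values)
        h5.attrs["frequencies_hz"] = grid.frequencies
    write_table(index, run_dir / "blockmeans_index.tsv")
    spec_df = pd.DataFrame(
        spectrum.roi_by_scale,
        columns=[f"{_mhz(f):.4f}" for f in spectrum.frequencies],
    )
    spec_df.insert(0, "roi", list(spectrum.roi_labels))
    write_table(spec_df, run_dir / "spectrum.tsv")
    if problems:
        (run_dir / "window_problems.txt").write_text("\n".join(problems) + "\n")


def _load_spectrum(run_dir: Path) -> CoherenceSpectrum:
    df = read_table(run_dir / "spectrum.tsv")
    freqs = np.array([float(c) for c in df.columns[1:]]) / 1000.0
    return CoherenceSpectrum(
        frequencies=freqs,
        roi_by_scale=df.iloc[:, 1:].to_numpy(dtype=float),
        roi_labels=tuple(df["roi"].tolist()),
    )


def stage_spectrum(run_dir: str | Path, analysis: AnalysisConfig) -> None:
    """Trim the saved spectrum and write the selected band (mHz)."""
    run_dir = Path(run_dir)
    spectrum = _load_spectrum(run_dir)
    f_low, f_high, f_peak = band_from_spectrum(spectrum, analysis)
    write_table(
        pd.DataFrame(
            [
                {
                    "f_low_mhz": _mhz(f_low),
                    "f_high_mhz": _mhz(f_high),
                    "f_peak_mhz": _mhz(f_peak),
                    "override": analysis.band_override is not None,
                }
            ]
        ),
        run_dir / "band.tsv",
    )


def stage_extract(run_dir: str | Path, analysis: AnalysisConfig) -> None:
    run_dir = Path(run_dir)
    index = read_table(run_dir / "blockmeans_index.tsv")
    with h5py.File(run_dir / "blockmeans.h5", "r") as h5:
        values = h5["values"][()]
        freqs = np.asarray(h5.attrs["frequencies_hz"])
    band_df = read_table(run_dir / "band.tsv")
    band = (
        band_df["f_low_mhz"].iloc[0] / 1000.0,
        band_df["f_high_mhz"].iloc[0] / 1000.0,
    )
    dyads, _ = load_cohort(run_dir)
    grid = _grid_for(dyads, analysis)
    block_terms = terms_from_blockmeans(index, values, grid, band)
    write_table(block_terms, run_dir / "block_terms.tsv")
    write_table(aggregate_table(block_terms), run_dir / "raw_table.tsv")


def stage_baseline(run_dir: str | Path, analysis: AnalysisConfig) -> None:
    run_dir = Path(run_dir)
    dyads, events = load_cohort(run_dir)
    manifest = manifest_from_dyads(dyads)
    band_df = read_table(run_dir / "band.tsv")
    band = (
        band_df["f_low_mhz"].iloc[0] / 1000.0,
        band_df["f_high_mhz"].iloc[0] / 1000.0,
    )
    plan = make_surrogate_plan(manifest, analysis.n_permutations, analysis.seed)
    surrogate_terms = compute_surrogate_terms(
        dyads, events, analysis, band, plan
    )
    baseline_table = compute_baseline(plan, surrogate_terms)
    raw = read_table(run_dir / "raw_table.tsv")
    raw["missing"] = raw["missing"].astype(bool)
    corrected = subtract_baseline(
        raw, baseline_table, manifest, analysis.baseline_strategy
    )
    write_table(plan.to_frame(), run_dir / "surrogate_plan.tsv")
    write_table(surrogate_terms, run_dir / "surrogate_terms.tsv")
    write_table(baseline_table, run_dir / "baseline.tsv")
    write_table(corrected, run_dir / "corrected.tsv")


def stage_stats(run_dir: str | Path, analysis: AnalysisConfig) -> None:
    run_dir = Path(run_dir)
    corrected = read_table(run_dir / "corrected.tsv")
    corrected["missing"] = corrected["missing"].astype(bool)
    stats = run_group_stats(
        corrected, fdr_q=analysis.fdr_q, sqrt_before_z=analysis.sqrt_before_z
    )
    write_table(stats["omnibus"], run_dir / "omnibus.tsv")
    write_table(stats["posthoc"], run_dir / "posthoc.tsv")
    write_table(stats["outlier_log"], run_dir / "outliers.tsv")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> AnalysisResult:
    """Simulate (or reuse) a cohort in ``out_dir`` and run every stage.

    ``seed`` overrides both the simulation and the surrogate-plan seed so a
    single integer reproduces the whole run.
    """
    sim = config.simulation
    analysis = config.analysis
    if seed is not None:
        sim = dataclasses.replace(sim, seed=int(seed))
        analysis = dataclasses.replace(analysis, seed=int(seed))
    out = Path(out_dir)
    stage_simulate(sim, out)
    dyads, events = load_cohort(out)
    result = analyze_cohort(dyads, events, analysis)
    stage_wtc_outputs(result, out)
    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": sim.seed,
        "band_mhz": [_mhz(f) for f in result.band],
        "kept_rois": result.kept_rois,
        "n_window_problems": len(result.window_problems),
        "analysis": dataclasses.asdict(analysis),
    }
    write_config(log, out / "run_log.yaml")
    return result


def stage_wtc_outputs(result: AnalysisResult, out: Path) -> None:
    """Persist every stage table of an in-memory result."""
    spec_df = pd.DataFrame(
        result.spectrum.roi_by_scale,
        columns=[f"{_mhz(f):.4f}" for f in result.spectrum.frequencies],
    )
    spec_df.insert(0, "roi", list(result.spectrum.roi_labels))
    write_table(spec_df, out / "spectrum.tsv")
    write_table(
        pd.DataFrame(
            [
                {
                    "f_low_mhz": _mhz(result.band[0]),
                    "f_high_mhz": _mhz(result.band[1]),
                    "f_peak_mhz": _mhz(result.band[2]),
                }
            ]
        ),
        out / "band.tsv",
    )
    write_table(result.block_terms, out / "block_terms.tsv")
    write_table(result.raw_table, out / "raw_table.tsv")
    write_table(result.surrogate_plan.to_frame(), out / "surrogate_plan.tsv")
    write_table(result.surrogate_terms, out / "surrogate_terms.tsv")
    write_table(result.baseline_table, out / "baseline.tsv")
    write_table(result.corrected_table, out / "corrected.tsv")
    write_table(result.omnibus, out / "omnibus.tsv")
    write_table(result.posthoc, out / "posthoc.tsv")
    write_table(result.outlier_log, out / "outliers.tsv")
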