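"""Synthetic dyadic hyperscanning cohorts with known coupling ground truth.

The generator emulates the study design the analysis targets: dyads scanned
simultaneously on two scanners, two runs of ~775 volumes at TR = 1.5 s, and
five task blocks per run (cooperation, communication, competition, solo,
watch) presented in a fixed order with the solo/watch roles swapped between
runs.  Each trial opens with a 5-s planning phase, shows the stimulus after a
variable delay (mean 1.05 s) and closes with feedback whose duration (mean
2.55 s) is yoked to the delay so every trial lasts equally long.

ROI time series are AR(1) noise (optionally 1/f-shaped), independent across
subjects and ROIs.  Interbrain coupling is injected additively as a
band-limited analytic component shared within a dyad during the blocks of
selected conditions, with a configurable amplitude (as a multiple of the
noise SD) and phase lag.  ``GroundTruth`` records exactly which
dyad x ROI x condition cells are coupled.

Randomness is split into named streams keyed off the master seed (schedule,
per-subject noise, per-dyad coupling and response times, missingness), so
the same seed reproduces the cohort bit for bit and adding dyads never
perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .exceptions import ConfigError

__all__ = [
    "CONDITIONS",
    "NoiseModel",
    "CouplingSpec",
    "RTModel",
    "SimulationConfig",
    "DyadRecord",
    "simulate_cohort",
    "simulate_rts",
    "demo_signal_pair",
]

CONDITIONS = ("cooperation", "communication", "competition", "solo", "watch")

# sub-stream tags for the seeded RNG tree
_STREAM_SCHEDULE = 0
_STREAM_NOISE = 1
_STREAM_COUPLING = 2
_STREAM_RT = 3
_STREAM_MISSING = 4


@dataclass(frozen=True)
class NoiseModel:
    """Background BOLD-like noise: AR(1) with optional 1/f spectral shaping."""

    ar1: float = 0.3
    one_over_f_exponent: float = 0.0
    sd: float = 1.0


@dataclass(frozen=True)
class CouplingSpec:
    """Band-limited component shared within a dyad in selected cells.

    amplitude is expressed as a multiple of the noise SD; phase_lag (rad) is
    applied to the second subject relative to the first.
    """

    rois: tuple[int, ...]
    conditions: tuple[str, ...]
    band: tuple[float, float]
    amplitude: float
    phase_lag: float = 0.0


@dataclass(frozen=True)
class RTModel:
    """Bivariate log-free Gaussian response-time model for one condition."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    rho: float = 0.0


def _default_rt_models() -> dict[str, RTModel]:
    return {
        "cooperation": RTModel(1.9, 1.9, 0.45, 0.45, 0.25),
        "communication": RTModel(1.8, 1.8, 0.35, 0.35, 0.45),
        "competition": RTModel(0.55, 0.55, 0.12, 0.12, 0.0),
        "solo": RTModel(0.7, 0.7, 0.15, 0.15, 0.0),
        "watch": RTModel(0.7, 0.7, 0.15, 0.15, 0.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of a synthetic cohort."""

    n_dyads: int = 12
    n_rois: int = 10
    tr: float = 1.5
    n_volumes_per_run: int = 775
    n_runs: int = 2
    block_order: tuple[str, ...] = CONDITIONS
    trial_count_per_block: int = 18
    planning_duration: float = 5.0
    mean_stim_delay: float = 1.05
    mean_feedback_duration: float = 2.55
    response_window: float = 2.5
    inter_block_rest: float = 15.0
    initial_rest: float = 12.0
    coupling: tuple[CouplingSpec, ...] = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    rt_models: dict[str, RTModel] = field(default_factory=_default_rt_models)
    missing_data_rate: float = 0.0
    seed: int = 0

    @property
    def trial_duration(self) -> float:
        """Constant trial length: delay and feedback are yoked."""
        return (
            self.planning_duration
            + self.response_window
            + self.mean_stim_delay
            + self.mean_feedback_duration
        )

    @property
    def run_duration(self) -> float:
        n_blocks = len(self.block_order)
        return (
            self.initial_rest
            + n_blocks * self.trial_count_per_block * self.trial_duration
            + (n_blocks - 1) * self.inter_block_rest
        )

    def validate(self) -> None:
        if self.tr <= 0:
            raise ConfigError("tr must be positive")
        if self.n_dyads < 1 or self.n_rois < 1 or self.n_runs < 1:
            raise ConfigError("n_dyads, n_rois and n_runs must be >= 1")
        if set(self.block_order) - set(CONDITIONS):
            raise ConfigError(
                f"unknown condition labels: {set(self.block_order) - set(CONDITIONS)}"
            )
        nyq = 0.5 / self.tr
        for spec in self.coupling:
            f1, f2 = spec.band
            if not (0.0 < f1 <= f2 < nyq):
                raise ConfigError(
                    f"coupling band {spec.band} outside (0, Nyquist={nyq:.4g})"
                )
            if set(spec.conditions) - set(CONDITIONS):
                raise ConfigError(f"unknown coupling conditions {spec.conditions}")
            if any(r < 0 or r >= self.n_rois for r in spec.rois):
                raise ConfigError(f"coupling ROI out of range in {spec.rois}")
        if self.run_duration > self.n_volumes_per_run * self.tr:
            raise ConfigError(
                f"block schedule ({self.run_duration:.1f} s) exceeds run length "
                f"({self.n_volumes_per_run * self.tr:.1f} s)"
            )
        if not 0.0 <= self.missing_data_rate <= 1.0:
            raise ConfigError("missing_data_rate must lie in [0, 1]")


@dataclass
class DyadRecord:
    """One scanned pair: identities, scanner assignment and ROI series."""

    dyad_id: str
    subject_a_id: str
    subject_b_id: str
    scanner_of_a: str
    scanner_of_b: str
    tr: float
    series_a: np.ndarray  # (n_runs, n_volumes, n_rois)
    series_b: np.ndarray
    roi_missing_a: np.ndarray  # (n_rois,) fraction of unusable data
    roi_missing_b: np.ndarray


# --------------------------------------------------------------------------
# schedule / events


def _block_order_for_run(config: SimulationConfig, run: int) -> tuple[str, ...]:
    """Fixed block order; solo and watch swap positions on odd runs."""
    order = list(config.block_order)
    if run % 2 == 1 and "solo" in order and "watch" in order:
        i, j = order.index("solo"), order.index("watch")
        order[i], order[j] = order[j], order[i]
    return tuple(order)


def _build_schedule(config: SimulationConfig, run: int) -> pd.DataFrame:
    """Trial-level schedule for one run, shared by every dyad.

    Stimulus delays are pseudo-randomised from the schedule stream so all
    subjects see the same timing, as in a non-randomised design.
    """
    rng = np.random.default_rng([config.seed, _STREAM_SCHEDULE, run])
    rows = []
    t = config.initial_rest
    for b, cond in enumerate(_block_order_for_run(config, run)):
        block_start = t
        for j in range(config.trial_count_per_block):
            delay = rng.uniform(
                config.mean_stim_delay - 0.5, config.mean_stim_delay + 0.5
            )
            planning_on = t
            stim_on = planning_on + config.planning_duration + delay
            fb_on = (
                planning_on
                + config.planning_duration
                + delay
                + config.response_window
            )
            fb_dur = (
                config.mean_stim_delay + config.mean_feedback_duration - delay
            )
            rows.append((planning_on, config.planning_duration, cond, b, j, "planning"))
            rows.append((stim_on, config.response_window, cond, b, j, "stimulus"))
            rows.append((fb_on, fb_dur, cond, b, j, "feedback"))
            t = planning_on + config.trial_duration
        rows.append((block_start, t - block_start, cond, b, -1, "block"))
        t += config.inter_block_rest
    df = pd.DataFrame(
        rows, columns=["onset", "duration", "trial_type", "block", "trial", "event"]
    )
    return df.sort_values(["onset", "event"], kind="stable").reset_index(drop=True)


def simulate_rts(
    condition: str,
    model: RTModel | None = None,
    n_trials: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw (rt_a, rt_b) pairs from a correlated bivariate Gaussian.

    Values are floored at 0.05 s.  A "fast responder" regime (means below
    1.6 s) exercises the response-time adjustment downstream.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if model is None:
        model = _default_rt_models()[condition]
    if model.sd_a < 0 or model.sd_b < 0:
        raise ConfigError("response-time SDs must be non-negative")
    if not -1.0 <= model.rho <= 1.0:
        raise ConfigError("rho must lie in [-1, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cov = np.array(
        [
            [model.sd_a**2, model.rho * model.sd_a * model.sd_b],
            [model.rho * model.sd_a * model.sd_b, model.sd_b**2],
        ]
    )
    draws = rng.multivariate_normal(
        [model.mean_a, model.mean_b], cov, size=n_trials, method="eigh"
    )
    return np.maximum(draws, 0.05)


def _events_for_dyad(
    config: SimulationConfig, schedule: pd.DataFrame, run: int, dyad_idx: int
) -> pd.DataFrame:
    """Attach per-dyad response times to the shared schedule."""
    rng = np.random.default_rng([config.seed, _STREAM_RT, dyad_idx, run])
    events = schedule.copy()
    events["response_time_a"] = np.nan
    events["response_time_b"] = np.nan
    stim = events["event"] == "stimulus"
    for cond in events.loc[stim, "trial_type"].unique():
        sel = stim & (events["trial_type"] == cond)
        n = int(sel.sum())
        rts = simulate_rts(cond, config.rt_models.get(cond), n, rng)
        if cond == "solo":  # subject A responds, B watches
            events.loc[sel, "response_time_a"] = rts[:, 0]
        elif cond == "watch":  # roles reversed
            events.loc[sel, "response_time_b"] = rts[:, 1]
        else:
            events.loc[sel, "response_time_a"] = rts[:, 0]
            events.loc[sel, "response_time_b"] = rts[:, 1]
    return events


# --------------------------------------------------------------------------
# signal generation


def _noise(
    rng: np.random.Generator, n: int, model: NoiseModel, dt: float
) -> np.ndarray:
    """AR(1) noise normalised to the target SD, optionally 1/f-shaped."""
    eps = rng.standard_normal(n)
    if model.one_over_f_exponent > 0:
        spec = np.fft.rfft(eps)
        f = np.fft.rfftfreq(n, dt)
        w = np.ones_like(f)
        w[1:] = f[1:] ** (-model.one_over_f_exponent / 2.0)
        w[0] = w[1]
        eps = np.fft.irfft(spec * w, n)
        eps /= eps.std()
    x = _signal.lfilter([1.0], [1.0, -model.ar1], eps)
    x *= model.sd * math.sqrt(1.0 - model.ar1**2)
    if model.one_over_f_exponent > 0:
        x *= model.sd / max(x.std(), 1e-12)
    return x


def _coupled_component(
    rng: np.random.Generator,
    t: np.ndarray,
    band: tuple[float, float],
    n_tones: int = 8,
) -> np.ndarray:
    """Unit-variance analytic narrow-band process on the given time support."""
    freqs = rng.uniform(band[0], band[1], n_tones)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_tones)
    z = np.exp(1j * (2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]))
    z = z.sum(axis=0)
    sd = z.real.std()
    return z / max(sd, 1e-12)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[DyadRecord], dict[tuple[str, int], pd.DataFrame], pd.DataFrame]:
    """Generate a cohort of dyads with events and coupling ground truth.

    Returns ``(dyads, events, ground_truth)`` where ``events`` maps
    (dyad_id, run) to a BIDS-style event table and ``ground_truth`` lists
    every coupled dyad x ROI x condition cell.
    """
    config.validate()
    schedules = [_build_schedule(config, r) for r in range(config.n_runs)]
    n_vol = config.n_volumes_per_run
    t_grid = np.arange(n_vol) * config.tr

    dyads: list[DyadRecord] = []
    events: dict[tuple[str, int], pd.DataFrame] = {}
    truth_rows = []
    missing_rng = np.random.default_rng([config.seed, _STREAM_MISSING])

    for d in range(config.n_dyads):
        dyad_id = f"dyad-{d + 1:02d}"
        sa, sb = f"sub-{2 * d + 1:03d}", f"sub-{2 * d + 2:03d}"
        series = []
        for subj_idx in (2 * d, 2 * d + 1):
            rng = np.random.default_rng([config.seed, _STREAM_NOISE, subj_idx])
            arr = np.empty((config.n_runs, n_vol, config.n_rois))
            for r in range(config.n_runs):
                for roi in range(config.n_rois):
                    arr[r, :, roi] = _noise(rng, n_vol, config.noise, config.tr)
            series.append(arr)
        ser_a, ser_b = series

        crng = np.random.default_rng([config.seed, _STREAM_COUPLING, d])
        for spec in config.coupling:
            if spec.amplitude == 0:
                continue
            amp = spec.amplitude * config.noise.sd
            for roi in spec.rois:
                for cond in spec.conditions:
                    for r in range(config.n_runs):
                        blocks = schedules[r]
                        sel = (blocks["event"] == "block") & (
                            blocks["trial_type"] == cond
                        )
                        for _, row in blocks[sel].iterrows():
                            lo = int(np.ceil(row["onset"] / config.tr))
                            hi = int(
                                np.floor((row["onset"] + row["duration"]) / config.tr)
                            )
                            z = _coupled_component(crng, t_grid[lo:hi], spec.band)
                            ser_a[r, lo:hi, roi] += amp * z.real
                            ser_b[r, lo:hi, roi] += amp * (
                                z * np.exp(-1j * spec.phase_lag)
                            ).real
                    truth_rows.append(
                        {
                            "dyad": dyad_id,
                            "roi": roi,
                            "condition": cond,
                            "amplitude": spec.amplitude,
                            "f_low": spec.band[0],
                            "f_high": spec.band[1],
                            "phase_lag": spec.phase_lag,
                        }
                    )

        miss = (
            missing_rng.uniform(size=(2, config.n_rois)) < config.missing_data_rate
        ).astype(float)
        dyads.append(
            DyadRecord(
                dyad_id=dyad_id,
                subject_a_id=sa,
                subject_b_id=sb,
                scanner_of_a="scanner-1",
                scanner_of_b="scanner-2",
                tr=config.tr,
                series_a=ser_a,
                series_b=ser_b,
                roi_missing_a=miss[0],
                roi_missing_b=miss[1],
            )
        )
        for r in range(config.n_runs):
            events[(dyad_id, r)] = _events_for_dyad(config, schedules[r], r, d)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "dyad",
            "roi",
            "condition",
            "amplitude",
            "f_low",
            "f_high",
            "phase_lag",
        ],
    )
    return dyads, events, truth


def manifest_from_dyads(dyads: list[DyadRecord]) -> pd.DataFrame:
    """Dyad <-> subject <-> scanner manifest table."""
    return pd.DataFrame(
        {
            "dyad": [d.dyad_id for d in dyads],
            "subject_a": [d.subject_a_id for d in dyads],
            "subject_b": [d.subject_b_id for d in dyads],
            "scanner_a": [d.scanner_of_a for d in dyads],
            "scanner_b": [d.scanner_of_b for d in dyads],
        }
    )


def demo_signal_pair(
    duration: float = 1600.0,
    dt: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    freqs: tuple[float, float] = (0.005, 0.040),
    spans: tuple[tuple[float, float], ...] = ((0.0, 0.7), (0.35, 1.0)),
) -> tuple[np.ndarray, np.ndarray]:
    """Classic WTC demonstration pair: partially overlapping sine components
    in X and matching cosine components in Y, plus independent Gaussian noise.

    ``spans`` gives each component's on-interval as fractions of the record;
    with two tones at 5 and 40 mHz the coherence map shows two phase-locked
    clusters with a pi/2 cross-phase.
    """
    if duration < 3.0 / min(freqs):
        raise ConfigError(
            "duration must cover at least 3 cycles of the slowest component"
        )
    t = np.arange(0.0, duration, dt)
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, t.size)
    y = rng.normal(0.0, noise_sd, t.size)
    for f, (lo, hi) in zip(freqs, spans):
        on = (t >= lo * duration) & (t < hi * duration)
        x += np.where(on, np.sin(2.0 * np.pi * f * t), 0.0)
        y += np.where(on, np.cos(2.0 * np.pi * f * t), 0.0)
    return x, y
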