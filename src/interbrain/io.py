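"""Readers and writers for on-disk artifacts.

Tables travel as TSV, ROI series as per-subject TSV or a single HDF5
container (datasets /<subject>/run-<r>, attributes tr and roi_labels),
events as BIDS-style events.tsv, configuration as YAML.  Frequencies are
reported in mHz in output files (the field's idiom) and held in Hz in
memory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .simulate import (
    CouplingSpec,
    DyadRecord,
    NoiseModel,
    RTModel,
    SimulationConfig,
)

__all__ = [
    "read_events",
    "write_events",
    "read_series_tsv",
    "write_series_tsv",
    "read_series_hdf5",
    "write_series_hdf5",
    "read_config",
    "write_config",
    "write_table",
    "read_table",
]

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "block",
    "trial",
    "event",
    "response_time_a",
    "response_time_b",
]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    df = events[EVENT_COLUMNS].copy()
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6g")


def read_events(path: str | Path) -> pd.DataFrame:
    """Parse a BIDS-style events.tsv; raises naming every missing column."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required columns {missing}")
    bad = df.index[df["onset"].isna() | df["duration"].isna()]
    if len(bad):
        raise ConfigError(
            f"{path}: malformed rows (lines {[int(i) + 2 for i in bad]})"
        )
    return df


def write_series_tsv(
    series: np.ndarray, path: str | Path, roi_labels: list[str] | None = None
) -> None:
    """One run of one subject as TSV, header = ROI labels."""
    if roi_labels is None:
        roi_labels = [f"roi-{i:03d}" for i in range(series.shape[1])]
    pd.DataFrame(series, columns=roi_labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_series_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ConfigError(
            f"{path}: NaN cells are not allowed; encode missingness in the manifest"
        )
    return arr, list(df.columns)


def write_series_hdf5(
    dyads: list[DyadRecord], path: str | Path, roi_labels: list[str] | None = None
) -> None:
    """All subjects' runs in one container: /<subject>/run-<r>."""
    with h5py.File(path, "w") as h5:
        for d in dyads:
            for subj, series, scanner in (
                (d.subject_a_id, d.series_a, d.scanner_of_a),
                (d.subject_b_id, d.series_b, d.scanner_of_b),
            ):
                grp = h5.create_group(subj)
                grp.attrs["tr"] = d.tr
                grp.attrs["dyad"] = d.dyad_id
                grp.attrs["scanner"] = scanner
                if roi_labels is not None:
                    grp.attrs["roi_labels"] = roi_labels
                for r in range(series.shape[0]):
                    grp.create_dataset(f"run-{r}", data=series[r])


def read_series_hdf5(path: str | Path) -> dict[str, dict]:
    """Return {subject: {"tr", "dyad", "scanner", "series": (runs, t, rois)}}."""
    out: dict[str, dict] = {}
    with h5py.File(path, "r") as h5:
        for subj in h5:
            grp = h5[subj]
            if "tr" not in grp.attrs:
                raise ConfigError(f"{path}:/{subj} lacks the tr attribute")
            runs = sorted(grp.keys())
            series = np.stack([grp[r][()] for r in runs])
            if np.isnan(series).any():
                raise ConfigError(f"{path}:/{subj}: NaN values are not allowed")
            out[subj] = {
                "tr": float(grp.attrs["tr"]),
                "dyad": str(grp.attrs.get("dyad", "")),
                "scanner": str(grp.attrs.get("scanner", "")),
                "series": series,
            }
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


# --------------------------------------------------------------------------
# configuration round-trip


def _config_to_dict(config) -> dict:
    def unpack(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: unpack(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [unpack(v) for v in obj]
        return obj

    return unpack(config)


def write_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def _simulation_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    if "noise" in data:
        data["noise"] = NoiseModel(**data["noise"])
    if "coupling" in data:
        data["coupling"] = tuple(
            CouplingSpec(
                rois=tuple(c["rois"]),
                conditions=tuple(c["conditions"]),
                band=tuple(c["band"]),
                amplitude=c["amplitude"],
                phase_lag=c.get("phase_lag", 0.0),
            )
            for c in data["coupling"]
        )
    if "rt_models" in data:
        data["rt_models"] = {
            k: RTModel(**v) for k, v in data["rt_models"].items()
        }
    if "block_order" in data:
        data["block_order"] = tuple(data["block_order"])
    return SimulationConfig(**data)


def read_config(path: str | Path):
    """Load a PipelineConfig (or bare SimulationConfig) from YAML."""
    from .pipeline import AnalysisConfig, PipelineConfig

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "simulation" in data:
        analysis = data.get("analysis", {})
        if analysis.get("band_override") is not None:
            analysis["band_override"] = tuple(analysis["band_override"])
        return PipelineConfig(
            simulation=_simulation_from_dict(data["simulation"]),
            analysis=AnalysisConfig(**analysis),
        )
    return _simulation_from_dict(data)
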