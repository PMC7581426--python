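"""File formats: HDF5/CSV trace matrices, CSV tables, YAML configs.

HDF5 layout for traces: dataset ``traces`` (rois x time, float64) with attrs
``fs`` (Hz, required), ``units`` and ``channel``, plus a ``roi_ids`` string
dataset. The CSV fallback stores a ``time_s`` column followed by one column per
ROI; the sampling rate is recovered from the time grid. Motion traces use the
same layouts with a single ``speed`` row. All writers log their destination.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import MotionTrace, StimulusLog, TraceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "write_traces",
    "read_traces",
    "write_motion",
    "read_motion",
    "write_table",
    "read_event_table",
    "read_roi_table",
    "write_stimulus_log",
    "read_stimulus_log",
    "write_config",
    "read_config",
]


def write_traces(tm: TraceMatrix, path: str | Path) -> Path:
    """Write a TraceMatrix to ``.h5``/``.hdf5`` or ``.csv`` by extension."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("traces", data=tm.values)
            d.attrs["fs"] = tm.fs
            d.attrs["units"] = tm.units
            d.attrs["channel"] = tm.channel
            f.create_dataset("roi_ids", data=np.array(tm.roi_ids, dtype="S"))
    elif path.suffix == ".csv":
        df = pd.DataFrame(tm.values.T, columns=tm.roi_ids)
        df.insert(0, "time_s", tm.time)
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported trace format: {path.suffix}")
    logger.info("wrote %s traces (%d ROIs x %d frames) to %s",
                tm.channel, tm.n_rois, tm.n_frames, path)
    return path


def read_traces(
    path: str | Path, units: str | None = None, channel: str | None = None
) -> TraceMatrix:
    """Read a TraceMatrix from HDF5 or CSV; validates finiteness and metadata."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f["traces"]
            if "fs" not in d.attrs:
                raise ValueError(f"{path}: missing required 'fs' attribute")
            values = d[...]
            fs = float(d.attrs["fs"])
            u = units or str(d.attrs.get("units", "raw-F"))
            ch = channel or str(d.attrs.get("channel", "CF"))
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["roi_ids"][...]]
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: CSV traces need a 'time_s' header column")
        if df.isna().any().any():
            loc = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing cell at row {loc[0]}, column {df.columns[loc[1]]!r}"
            )
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise ValueError(f"{path}: need at least two timepoints")
        fs = 1.0 / float(np.mean(np.diff(t)))
        ids = [c for c in df.columns if c != "time_s"]
        values = df[ids].to_numpy(float).T
        u = units or "raw-F"
        ch = channel or "CF"
    else:
        raise ValueError(f"unsupported trace format: {path.suffix}")
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[:5]
        raise ValueError(f"{path}: non-finite values at {bad.tolist()}")
    return TraceMatrix(values, fs=fs, units=u, channel=ch, roi_ids=ids)


def write_motion(m: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("speed", data=m.speed)
            d.attrs["fs"] = m.fs
    elif path.suffix == ".csv":
        pd.DataFrame({"time_s": m.time, "speed_mm_s": m.speed}).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported motion format: {path.suffix}")
    logger.info("wrote motion trace (%d samples at %g Hz) to %s", m.speed.size, m.fs, path)
    return path


def read_motion(path: str | Path) -> MotionTrace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f["speed"]
            if "fs" not in d.attrs:
                raise ValueError(f"{path}: missing required 'fs' attribute")
            return MotionTrace(d[...], fs=float(d.attrs["fs"]))
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        fs = 1.0 / float(np.mean(np.diff(t)))
        return MotionTrace(df["speed_mm_s"].to_numpy(float), fs=fs)
    raise ValueError(f"unsupported motion format: {path.suffix}")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    logger.info("wrote table (%d rows) to %s", len(df), path)
    return path


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["first_peak"] = df["first_peak"].astype(bool)
    df["spike_count_est"] = df["spike_count_est"].astype("Int64")
    return df


def read_roi_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stimulus_log(stim: StimulusLog, path: str | Path) -> Path:
    path = Path(path)
    df = stim.to_frame()
    df["inter_trial_s"] = stim.inter_trial_s
    df.to_csv(path, index=False)
    logger.info("wrote stimulus log (%d puffs) to %s", len(df), path)
    return path


def read_stimulus_log(path: str | Path) -> StimulusLog:
    df = pd.read_csv(path)
    return StimulusLog(
        df["puff_time_s"].to_numpy(float),
        list(df["pressure"]),
        puff_duration_ms=float(df["puff_duration_ms"].iloc[0]) if len(df) else 30.0,
        inter_trial_s=float(df["inter_trial_s"].iloc[0]) if "inter_trial_s" in df and len(df) else 5.0,
    )


def write_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    logger.info("wrote config snapshot to %s", path)
    return path


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
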