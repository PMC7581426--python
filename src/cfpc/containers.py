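"""Core data containers shared across the pipeline.

The pipeline's main signal carrier is :class:`TraceMatrix` (ROIs x timepoints
fluorescence at a fixed sampling rate). Tabular objects -- ROI geometry, detected
events, CF-PC pair maps, stimulus logs -- are plain :class:`pandas.DataFrame`
objects with documented column schemas, constructed through the helpers below so
that every stage agrees on column names.

Conventions
-----------
* time is in seconds; frame ``k`` is stamped ``k / fs`` (frame start); windows are
  half-open ``(start, start + w]``.
* coordinates are in micrometres; ``x`` is mediolateral, ``y`` rostrocaudal.
* amplitudes are in SD units (z-score scale) unless a trace is tagged ``raw-F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraceMatrix",
    "MotionTrace",
    "StimulusLog",
    "make_roi_table",
    "make_event_table",
    "EVENT_COLUMNS",
    "ROI_COLUMNS",
    "PAIR_COLUMNS",
]

#: EventTable column schema: one row per detected calcium event.
EVENT_COLUMNS = ["roi_id", "time_s", "amplitude_sd", "first_peak", "spike_count_est"]

#: RoiTable column schema: per-ROI spatial metadata.
ROI_COLUMNS = ["roi_id", "x_um", "y_um", "radius_um", "channel"]

#: PairMap column schema (see :mod:`cfpc.pairing`).
PAIR_COLUMNS = ["cf_id", "pc_id", "category", "boundary_gap_um"]


@dataclass
class TraceMatrix:
    """ROIs x timepoints fluorescence matrix with sampling metadata.

    Parameters
    ----------
    values : ndarray, shape (n_rois, n_frames)
        Fluorescence samples. Must be finite.
    fs : float
        Sampling rate in Hz (32 Hz for two-photon traces by default).
    units : {"raw-F", "SD"}
        ``"SD"`` marks a z-scored trace (each row mean 0, SD 1).
    channel : {"CF", "PC", "activity", "neuropil"}
        Signal provenance tag.
    roi_ids : sequence of str
        Unique ROI identifiers, one per row.
    """

    values: np.ndarray
    fs: float
    units: str = "raw-F"
    channel: str = "CF"
    roi_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[None, :]
        if self.values.ndim != 2:
            raise ValueError("TraceMatrix values must be 2-D (rois x time)")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[:5]
            raise ValueError(f"TraceMatrix contains non-finite values, e.g. at {bad.tolist()}")
        if not (self.fs > 0):
            raise ValueError("sampling rate fs must be > 0")
        if not list(self.roi_ids):
            self.roi_ids = [f"roi{i:03d}" for i in range(self.values.shape[0])]
        self.roi_ids = list(self.roi_ids)
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError("roi_ids length must match number of rows")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be unique")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.fs

    @property
    def time(self) -> np.ndarray:
        """Frame timestamps in seconds (frame start convention)."""
        return np.arange(self.n_frames) / self.fs

    def row(self, roi_id: str) -> np.ndarray:
        return self.values[self.roi_ids.index(roi_id)]

    def copy_with(self, **kwargs) -> "TraceMatrix":
        return replace(self, **kwargs)


@dataclass
class MotionTrace:
    """Forepaw movement speed sampled at ``fs`` (64 Hz by default), in mm/s."""

    speed: np.ndarray
    fs: float = 64.0

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float).ravel()
        if not (self.fs > 0):
            raise ValueError("fs must be > 0")
        if not np.all(np.isfinite(self.speed)):
            raise ValueError("MotionTrace contains non-finite samples")
        if np.any(self.speed < 0):
            raise ValueError("speed must be nonnegative")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.speed.size) / self.fs

    @property
    def duration(self) -> float:
        return self.speed.size / self.fs


# psi values delivered for the two pressure levels.
PRESSURE_PSI = {"P1": 20.0, "P2": 50.0}


@dataclass
class StimulusLog:
    """Air-puff stimulation protocol: 30 ms periocular puffs at 5 s intervals.

    ``pressures`` holds one label ("P1" = 20 psi or "P2" = 50 psi) per puff.
    """

    puff_times: np.ndarray
    pressures: Sequence[str]
    puff_duration_ms: float = 30.0
    inter_trial_s: float = 5.0

    def __post_init__(self) -> None:
        self.puff_times = np.asarray(self.puff_times, dtype=float).ravel()
        self.pressures = list(self.pressures)
        if len(self.pressures) != self.puff_times.size:
            raise ValueError("one pressure label per puff required")
        unknown = set(self.pressures) - set(PRESSURE_PSI)
        if unknown:
            raise ValueError(f"unknown pressure labels: {sorted(unknown)}")
        if self.puff_times.size:
            gaps = np.diff(self.puff_times)
            if np.any(gaps <= 0):
                raise ValueError("puff times must be strictly increasing")
            if np.any(gaps < self.puff_duration_ms / 1000.0):
                raise ValueError("puff spacing must be at least the puff duration")
        if self.puff_duration_ms <= 0 or self.inter_trial_s <= 0:
            raise ValueError("puff duration and inter-trial interval must be positive")

    @property
    def psi(self) -> np.ndarray:
        return np.array([PRESSURE_PSI[p] for p in self.pressures])

    @classmethod
    def regular(
        cls,
        n_puffs: int,
        pressure: str | Sequence[str] = "P1",
        start: float = 2.0,
        inter_trial_s: float = 5.0,
        puff_duration_ms: float = 30.0,
    ) -> "StimulusLog":
        """Evenly spaced protocol starting at ``start`` seconds."""
        times = start + inter_trial_s * np.arange(n_puffs)
        if isinstance(pressure, str):
            pressures = [pressure] * n_puffs
        else:
            pressures = list(pressure)
        return cls(times, pressures, puff_duration_ms, inter_trial_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "puff_time_s": self.puff_times,
                "pressure": self.pressures,
                "psi": self.psi,
                "puff_duration_ms": self.puff_duration_ms,
            }
        )


def make_roi_table(
    roi_ids: Sequence[str],
    x_um: np.ndarray,
    y_um: np.ndarray,
    radius_um: np.ndarray | float = 2.0,
    channel: str = "CF",
) -> pd.DataFrame:
    """Build a RoiTable DataFrame (columns: roi_id, x_um, y_um, radius_um, channel)."""
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    r = np.broadcast_to(np.asarray(radius_um, dtype=float), x.shape).copy()
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ROI coordinates must be finite")
    if np.any(r < 0):
        raise ValueError("extent radius must be >= 0")
    return pd.DataFrame(
        {"roi_id": list(roi_ids), "x_um": x, "y_um": y, "radius_um": r, "channel": channel}
    )


def make_event_table(rows: Sequence[dict] | pd.DataFrame | None = None) -> pd.DataFrame:
    """Build an EventTable DataFrame, sorted by (roi_id, time_s)."""
    if rows is None or (hasattr(rows, "__len__") and len(rows) == 0):
        return pd.DataFrame(
            {
                "roi_id": pd.Series(dtype=str),
                "time_s": pd.Series(dtype=float),
                "amplitude_sd": pd.Series(dtype=float),
                "first_peak": pd.Series(dtype=bool),
                "spike_count_est": pd.Series(dtype="Int64"),
            }
        )
    df = pd.DataFrame(rows)
    if "first_peak" not in df:
        df["first_peak"] = False
    if "spike_count_est" not in df:
        df["spike_count_est"] = pd.Series([pd.NA] * len(df), dtype="Int64")
    df = df[EVENT_COLUMNS]
    df = df.sort_values(["roi_id", "time_s"], kind="stable").reset_index(drop=True)
    dup = df.duplicated(subset=["roi_id", "time_s"])
    if dup.any():
        raise ValueError("duplicate (roi_id, time_s) rows in EventTable")
    return df
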