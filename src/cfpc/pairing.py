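"""CF-PC pairing: geometric classification of presynaptic-postsynaptic ROI
relations, per-category signal correlation, and paired-amplitude regression.

A CF varicosity and a PC dendrite whose boundaries lie within 1 um are treated
as a putative synaptic pair; other combinations are 'neighboring unpaired'
(boundary gap <= 30 um) or 'distant unpaired' (> 30 um). For paired ROIs the
regression of PC on CF event amplitudes measures the translation gain (the
slope relating presynaptic to postsynaptic transient size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TraceMatrix
from .stimulus import GroupComparison, compare_groups

__all__ = [
    "classify_pairs",
    "pair_signal_correlation",
    "collect_amplitude_pairs",
    "amplitude_regression",
    "PAIRED",
    "NEIGHBORING",
    "DISTANT",
    "RegressionSummary",
]

PAIRED = "paired"
NEIGHBORING = "neighboring_unpaired"
DISTANT = "distant_unpaired"

PAIRED_GAP_UM = 1.0
NEIGHBOR_GAP_UM = 30.0


def classify_pairs(cf_rois: pd.DataFrame, pc_rois: pd.DataFrame) -> pd.DataFrame:
    """Classify every CF x PC combination by boundary gap.

    boundary_gap = centroid distance - (r_cf + r_pc), floored at 0. Gap < 1 um
    qualifies as 'paired'; qualifying combinations are assigned one-to-one in
    order of increasing centroid distance (overlapping ROIs all floor to gap 0,
    so the unclipped distance breaks the ties), and each CF and each PC joins
    at most one pair. Remaining qualifying combinations fall back to
    'neighboring_unpaired'. Gaps in [1, 30] um are 'neighboring_unpaired',
    beyond 30 um 'distant_unpaired'.
    """
    for tbl, chan in ((cf_rois, "CF"), (pc_rois, "PC")):
        if len(tbl) == 0:
            raise ValueError("ROI tables must be nonempty")
        if tbl["channel"].nunique() > 1:
            raise ValueError("mixed channels within one ROI table")
    cf = cf_rois.sort_values("roi_id").reset_index(drop=True)
    pc = pc_rois.sort_values("roi_id").reset_index(drop=True)
    dx = cf["x_um"].to_numpy()[:, None] - pc["x_um"].to_numpy()[None, :]
    dy = cf["y_um"].to_numpy()[:, None] - pc["y_um"].to_numpy()[None, :]
    dist = np.hypot(dx, dy)
    gap = dist - (
        cf["radius_um"].to_numpy()[:, None] + pc["radius_um"].to_numpy()[None, :]
    )
    gap = np.clip(gap, 0.0, None)

    # one-to-one paired assignment: greedy over qualifying combinations by
    # increasing centroid distance (stable under gap-0 ties from overlap)
    qual_i, qual_j = np.nonzero(gap < PAIRED_GAP_UM)
    order = np.argsort(dist[qual_i, qual_j], kind="stable")
    used_cf: set[int] = set()
    used_pc: set[int] = set()
    chosen: dict[int, int] = {}
    for k in order:
        i, j = int(qual_i[k]), int(qual_j[k])
        if i not in used_cf and j not in used_pc:
            chosen[i] = j
            used_cf.add(i)
            used_pc.add(j)

    rows = []
    for i, cf_id in enumerate(cf["roi_id"]):
        for j, pc_id in enumerate(pc["roi_id"]):
            g = float(gap[i, j])
            if chosen.get(i) == j:
                cat = PAIRED
            elif g <= NEIGHBOR_GAP_UM:
                cat = NEIGHBORING
            else:
                cat = DISTANT
            rows.append({"cf_id": cf_id, "pc_id": pc_id, "category": cat,
                         "boundary_gap_um": g})
    return pd.DataFrame(rows)


def pair_signal_correlation(
    pm: pd.DataFrame, cf: TraceMatrix, pc: TraceMatrix
) -> tuple[pd.DataFrame, GroupComparison | None]:
    """Pearson trace correlation per CF-PC combination, grouped by category.

    Returns the pair table with an ``r`` column plus a one-way ANOVA + Tukey
    comparison across categories (None if fewer than two categories have >= 2
    members).
    """
    if cf.n_frames != pc.n_frames or cf.fs != pc.fs:
        raise ValueError("CF and PC traces must share a time base")
    cf_idx = {r: i for i, r in enumerate(cf.roi_ids)}
    pc_idx = {r: i for i, r in enumerate(pc.roi_ids)}
    out = pm.copy()
    rs = []
    for cf_id, pc_id in zip(out["cf_id"], out["pc_id"]):
        a = cf.values[cf_idx[cf_id]]
        b = pc.values[pc_idx[pc_id]]
        if a.std() == 0 or b.std() == 0:
            rs.append(np.nan)
        else:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    out["r"] = rs

    groups = {
        cat: grp["r"].dropna().to_numpy()
        for cat, grp in out.groupby("category")
    }
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    comparison = compare_groups(usable) if len(usable) >= 2 else None
    return out, comparison


def collect_amplitude_pairs(
    pm: pd.DataFrame,
    cf_events: pd.DataFrame,
    pc_z: TraceMatrix,
    match_window: int = 5,
    first_peak_only: bool = True,
) -> pd.DataFrame:
    """Collect (CF amplitude, PC amplitude) pairs at CF event times.

    For each retained CF event of a paired combination, the PC amplitude is the
    maximum of the paired PC z-trace within +/- ``match_window`` frames of the
    event frame (default 5 frames ~ 156 ms at 32 Hz), tolerating small
    cross-channel peak jitter. Events whose window is clipped by a trace edge
    are flagged in the ``clipped`` column.
    """
    pairs = pm[pm["category"] == PAIRED]
    pc_idx = {r: i for i, r in enumerate(pc_z.roi_ids)}
    ev = cf_events[cf_events["first_peak"].astype(bool)] if first_peak_only else cf_events
    rows = []
    for cf_id, pc_id in zip(pairs["cf_id"], pairs["pc_id"]):
        trace = pc_z.values[pc_idx[pc_id]]
        for _, row in ev[ev["roi_id"] == cf_id].iterrows():
            f = int(round(row["time_s"] * pc_z.fs))
            lo, hi = f - match_window, f + match_window + 1
            clipped = lo < 0 or hi > trace.size
            lo, hi = max(lo, 0), min(hi, trace.size)
            rows.append(
                {"cf_id": cf_id, "pc_id": pc_id, "event_time_s": float(row["time_s"]),
                 "cf_amplitude": float(row["amplitude_sd"]),
                 "pc_amplitude": float(trace[lo:hi].max()), "clipped": clipped}
            )
    return pd.DataFrame(
        rows, columns=["cf_id", "pc_id", "event_time_s", "cf_amplitude",
                       "pc_amplitude", "clipped"]
    )


@dataclass
class RegressionSummary:
    """Per-pair OLS fits of PC on CF amplitudes with across-pair averages."""

    per_pair: pd.DataFrame  # columns: cf_id, pc_id, slope, intercept, r_squared, n
    mean_slope: float
    sem_slope: float
    mean_r_squared: float
    sem_r_squared: float

    def summary(self) -> str:
        return (
            f"Amplitude-pair regression over {len(self.per_pair)} CF-PC pairs\n"
            f"  mean slope = {self.mean_slope:.3f} +/- {self.sem_slope:.3f} SEM\n"
            f"  mean R^2   = {self.mean_r_squared:.3f} +/- {self.sem_r_squared:.3f} SEM"
        )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if x.size < 3:
        raise ValueError("regression needs n >= 3 amplitude pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in CF amplitudes; fit undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def amplitude_regression(aps: pd.DataFrame) -> RegressionSummary:
    """Ordinary least-squares of PC on CF amplitudes, per pair and averaged.

    The intercept is left free. Returns per-pair (slope, intercept, R^2, n) and
    the across-pair mean +/- SEM of slope and R^2.
    """
    rows = []
    for (cf_id, pc_id), grp in aps.groupby(["cf_id", "pc_id"]):
        x = grp["cf_amplitude"].to_numpy(float)
        y = grp["pc_amplitude"].to_numpy(float)
        slope, intercept, r2 = _ols(x, y)
        rows.append({"cf_id": cf_id, "pc_id": pc_id, "slope": slope,
                     "intercept": intercept, "r_squared": r2, "n": int(x.size)})
    if not rows:
        raise ValueError("no amplitude pairs to regress")
    per_pair = pd.DataFrame(rows)
    slopes = per_pair["slope"].to_numpy()
    r2s = per_pair["r_squared"].to_numpy()

    def sem(v):
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0

    return RegressionSummary(per_pair, float(slopes.mean()), sem(slopes),
                             float(r2s.mean()), sem(r2s))
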