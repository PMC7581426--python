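"""Parameter-recovery panels: the canned generator-analysis round trips used to
check that the pipeline recovers the quantities it was built to measure.

Each panel simulates sessions under the study conditions across a list of
seeds, runs the corresponding analysis stage, and returns the recovered
estimates next to the configured ground truth. They are used both by the test
suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import StimulusLog
from .pairing import (amplitude_regression, classify_pairs,
                      collect_amplitude_pairs, pair_signal_correlation)
from .signal_processing import (DeconvParams, deconvolve, detect_events,
                                event_frequency, first_peak_sample, zscore)
from .simulate import (SimParams, pc_noise_for_target_correlation,
                       pc_noise_for_target_r2, simulate_cf_population,
                       simulate_motion, simulate_paired_pc)
from .stimulus import amplitude_motion_regression, motion_latencies

__all__ = [
    "frequency_recovery_panel",
    "gain_recovery_panel",
    "paired_correlation_panel",
    "motion_null_panel",
    "motion_latency_panel",
]


def _process_events(trace, deconv: DeconvParams, first_peak_window: float = 0.5):
    z = zscore(trace)
    act = deconvolve(z, deconv)
    return z, first_peak_sample(detect_events(z, act, deconv), first_peak_window)


def frequency_recovery_panel(
    seeds, n_rois: int = 69, duration: float = 600.0
) -> pd.DataFrame:
    """Detected vs configured event frequency, one row per seed.

    Columns: seed, detected_hz (population mean), detected_sem_hz (across
    ROIs), true_hz (realized ground-truth rate).
    """
    dp = DeconvParams()
    rows = []
    for seed in seeds:
        p = SimParams(seed=int(seed), n_cf=n_rois, duration=duration)
        trace, rois, truth = simulate_cf_population(p)
        z = zscore(trace)
        det = detect_events(z, deconvolve(z, dp), dp)
        freq = event_frequency(det, duration, roi_ids=trace.roi_ids)
        rows.append(
            {"seed": int(seed), "detected_hz": freq.attrs["mean_hz"],
             "detected_sem_hz": freq.attrs["sem_hz"],
             "true_hz": len(truth.events) / (duration * n_rois)}
        )
    return pd.DataFrame(rows)


def gain_recovery_panel(
    seeds,
    n_pairs: int = 13,
    duration: float = 600.0,
    target_r2: float = 0.48,
) -> pd.DataFrame:
    """Across-pair mean amplitude-regression slope and R² per seed.

    PC noise follows the closed-form calibration
    sigma^2 = gain^2 var(a) (1 - R^2) / R^2 for the requested per-pair R².
    """
    dp = DeconvParams()
    rows = []
    for seed in seeds:
        p0 = SimParams(seed=int(seed), n_cf=n_pairs, n_pc=n_pairs, duration=duration)
        p = dataclasses.replace(
            p0, pc_noise_sd=float(pc_noise_for_target_r2(p0, target_r2))
        )
        cf_trace, cf_rois, truth = simulate_cf_population(p)
        _, cf_events = _process_events(cf_trace, dp)
        pc_trace, pc_rois = simulate_paired_pc(cf_trace, cf_rois, truth, p)
        pm = classify_pairs(cf_rois, pc_rois)
        aps = collect_amplitude_pairs(pm, cf_events, zscore(pc_trace))
        reg = amplitude_regression(aps)
        rows.append(
            {"seed": int(seed), "mean_slope": reg.mean_slope,
             "mean_r_squared": reg.mean_r_squared, "n_pairs": len(reg.per_pair)}
        )
    return pd.DataFrame(rows)


def paired_correlation_panel(
    seeds,
    n_pairs: int = 13,
    duration: float = 600.0,
    target_r: float = 0.605,
) -> pd.DataFrame:
    """Mean trace correlation per CF-PC category per seed.

    PC noise is calibrated so the true paired trace correlation equals
    ``target_r``. Columns: seed, paired_r, neighboring_r, distant_r,
    ordering_ok (paired > neighboring > distant).
    """
    rows = []
    for seed in seeds:
        p0 = SimParams(seed=int(seed), n_cf=n_pairs, n_pc=n_pairs, duration=duration)
        p = dataclasses.replace(
            p0, pc_noise_sd=float(pc_noise_for_target_correlation(p0, target_r))
        )
        cf_trace, cf_rois, truth = simulate_cf_population(p)
        pc_trace, pc_rois = simulate_paired_pc(cf_trace, cf_rois, truth, p)
        pm = classify_pairs(cf_rois, pc_rois)
        pm_r, _ = pair_signal_correlation(pm, zscore(cf_trace), zscore(pc_trace))
        g = pm_r.groupby("category")["r"].mean()
        paired = float(g.get("paired", np.nan))
        neigh = float(g.get("neighboring_unpaired", np.nan))
        dist = float(g.get("distant_unpaired", np.nan))
        rows.append(
            {"seed": int(seed), "paired_r": paired, "neighboring_r": neigh,
             "distant_r": dist,
             "ordering_ok": bool(paired > neigh > dist)}
        )
    return pd.DataFrame(rows)


def motion_null_panel(seeds, n_pairs: int = 2926) -> pd.DataFrame:
    """R² of regressing independent amplitudes on independent peak speeds.

    Event amplitudes and twitch peak speeds are drawn independently from the
    generator's marginals, so the regression is a true null; one row per seed.
    """
    p = SimParams()
    from .burst import forward_amplitude

    a_levels = forward_amplitude(np.arange(1, 10), p.calibration)
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        counts = rng.choice(np.arange(9), size=n_pairs, p=p.burst_dist)
        amps = a_levels[counts]
        speeds = np.maximum(
            rng.normal(p.twitch_peak_mean, p.twitch_peak_sd, n_pairs), 5.0
        )
        res = amplitude_motion_regression(amps, speeds)
        rows.append({"seed": int(seed), "r_squared": res["r_squared"],
                     "slope": res["slope"], "n": res["n"]})
    return pd.DataFrame(rows)


def motion_latency_panel(seed: int, n_trials: int = 100) -> pd.DataFrame:
    """Estimated vs true twitch latencies over ``n_trials`` puffs (one session).

    Returns the per-trial table from :func:`cfpc.stimulus.motion_latencies`;
    attrs carry the estimated means/SEMs plus the realized true means.
    """
    p = SimParams(seed=int(seed))
    stim = StimulusLog.regular(n_trials, pressure="P1")
    m, truth = simulate_motion(stim, p)
    lat = motion_latencies(m, stim)
    lat.attrs["true_mean_onset_ms"] = float(truth["onset_latency_ms"].mean())
    lat.attrs["true_mean_peak_ms"] = float(truth["peak_latency_ms"].mean())
    return lat
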