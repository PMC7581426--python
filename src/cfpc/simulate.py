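"""Ground-truth simulator for CF/PC calcium imaging sessions.

Generates the signal structure the analysis pipeline assumes, with full ground
truth for parameter-recovery testing:

* climbing-fiber (CF) varicosity traces: Poisson events at the resting rate
  (0.85 Hz), burst spike counts 1..9 mapped to saturating transient amplitudes,
  single-exponential indicator decay (tau = 0.4 s), distance-decaying population
  synchrony across a 208 um mediolateral field, white measurement noise;
* paired Purkinje-cell (PC) dendrite traces: gain-scaled copies of the CF drive
  plus independent noise and optional non-CF events;
* air-puff sessions: a stimulus-evoked CF event after each 30 ms puff, with the
  evoked burst-size distribution set per pressure level (P1 = 20, P2 = 50 psi);
* forepaw-twitch motion traces at 64 Hz with fixed puff-to-onset (23.2 ms) and
  puff-to-peak (57.6 ms) latencies, twitch size independent of CF amplitudes.

Amplitude scale. The generator emits traces in "SD-ready" units: with the default
parameters the analytic trace variance (Campbell's theorem: rate * E[a^2] * tau/2
plus noise variance) is ~1, so downstream z-scoring is approximately unit-gain and
ground-truth amplitudes are directly comparable with detected SD-unit amplitudes.
See docs/methods.md for the derivation and for the PC noise calibrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .burst import CalibrationCurve, forward_amplitude
from .containers import MotionTrace, StimulusLog, TraceMatrix, make_roi_table

__all__ = [
    "SimParams",
    "GroundTruth",
    "default_burst_dist",
    "default_intensity_map",
    "simulate_cf_population",
    "simulate_paired_pc",
    "simulate_stimulus_session",
    "simulate_motion",
    "render_traces",
    "cf_signal_variance",
    "cf_trace_variance",
    "amplitude_moments",
    "pc_noise_variance_matched",
    "pc_noise_for_target_correlation",
    "pc_noise_for_target_r2",
]


def default_burst_dist() -> np.ndarray:
    """Resting burst-size distribution over counts 1..9.

    Geometric-like (ratio 1/2) supported on 1..7: small bursts dominate at rest
    and the physiological range tops out around six or seven spikes.
    """
    p = np.zeros(9)
    p[:7] = 0.5 ** np.arange(1, 8)
    return p / p.sum()


def default_intensity_map() -> dict[str, np.ndarray]:
    """Evoked burst-size distributions per pressure level.

    Shifted binomials 1 + B(6, q) with q = 0.35 (P1) and q = 0.6 (P2); the higher
    pressure stochastically dominates the lower one, so evoked amplitude grows
    with stimulus strength.
    """
    from scipy.stats import binom

    out = {}
    for label, q in (("P1", 0.35), ("P2", 0.6)):
        p = np.zeros(9)
        p[:7] = binom.pmf(np.arange(7), 6, q)
        out[label] = p / p.sum()
    return out


@dataclass
class SimParams:
    """Simulation parameters. Defaults are the study conditions.

    Rates and kinetics come straight from the recorded regime (resting CF rate
    0.85 Hz, indicator decay tau 0.4 s, 32 Hz trace / 64 Hz motion sampling,
    208 um mediolateral field, 23.2 / 57.6 ms motion latencies); amplitude-model
    and synchrony defaults are derived analytically in docs/methods.md.
    """

    n_cf: int = 16
    n_pc: int = 0
    duration: float = 180.0          # s; 3-min resting-state sessions
    fs_trace: float = 32.0           # Hz
    fs_motion: float = 64.0          # Hz
    rate_cf: float = 0.85            # events/s per varicosity
    burst_dist: np.ndarray = field(default_factory=default_burst_dist)
    sync_p0: float = 0.5             # participation probability at distance 0
    sync_lambda: float = 150.0       # um, synchrony decay length
    field_span_um: float = 208.0     # mediolateral imaging-field width
    noise_sd: float = 0.3            # CF white-noise SD (SD-ready units)
    a_max: float = 4.0               # amplitude saturation level
    kappa: float = 2.0               # spikes; a(7) ~ 0.97 a_max
    tau_decay: float = 0.4           # s, indicator decay constant
    pc_gain: float = 0.61            # CF -> PC translation gain (SD-unit scale)
    pc_noise_sd: float | None = None  # None -> variance-matched (see methods)
    non_cf_rate: float = 0.0         # events/s of PC-only transients
    evoked_latency_ms: float = 60.0  # puff -> evoked CF event, mean
    evoked_jitter_ms: float = 20.0   # puff -> evoked CF event, SD
    motion_onset_ms: float = 23.2    # puff -> twitch onset, mean
    motion_onset_jitter_ms: float = 2.9
    motion_peak_ms: float = 57.6     # puff -> peak twitch speed, mean
    motion_peak_jitter_ms: float = 5.8
    twitch_peak_mean: float = 25.0   # mm/s
    twitch_peak_sd: float = 8.0      # mm/s
    twitch_decay_ms: float = 80.0    # half-cosine decay after the peak
    motion_baseline_sd: float = 0.4  # mm/s, rectified baseline noise
    seed: int = 0

    def __post_init__(self) -> None:
        self.burst_dist = np.asarray(self.burst_dist, dtype=float)
        if self.burst_dist.shape != (9,):
            raise ValueError("burst_dist must have 9 entries for spike counts 1..9")
        if np.any(self.burst_dist < 0) or abs(self.burst_dist.sum() - 1.0) > 1e-9:
            raise ValueError("burst_dist must be a probability vector over {1..9}")
        if self.n_cf < 1:
            raise ValueError("n_cf must be >= 1")
        if self.n_pc < 0 or self.n_pc > self.n_cf:
            raise ValueError("n_pc must lie in [0, n_cf]")
        for name in ("duration", "fs_trace", "fs_motion", "tau_decay", "a_max", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rate_cf <= 0:
            raise ValueError("rate_cf must be strictly positive")
        if not (0.0 <= self.sync_p0 <= 1.0):
            raise ValueError("sync_p0 must be a probability")
        if self.sync_lambda <= 0:
            raise ValueError("sync_lambda must be > 0")
        if self.noise_sd < 0 or self.non_cf_rate < 0:
            raise ValueError("noise levels and rates must be nonnegative")
        if self.pc_gain <= 0:
            raise ValueError("pc_gain must be > 0")
        if self.motion_peak_ms <= self.motion_onset_ms:
            raise ValueError("peak latency must exceed onset latency")

    @property
    def calibration(self) -> CalibrationCurve:
        return CalibrationCurve(a_max=self.a_max, kappa=self.kappa)

    @property
    def ar1_decay(self) -> float:
        return float(np.exp(-1.0 / (self.fs_trace * self.tau_decay)))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Simulator-side truth for recovery tests.

    ``events`` columns: roi_id, time_s, spike_count, amplitude (model amplitude
    a(n)), pop_event_id (-1 for private events), stim_evoked, pressure.
    """

    events: pd.DataFrame
    pair_assignments: pd.DataFrame | None = None
    pc_events: pd.DataFrame | None = None
    motion: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ev = self.events
        if len(ev):
            if (ev["time_s"] < 0).any():
                raise ValueError("ground-truth event times must be >= 0")
            if not ev["spike_count"].between(1, 9).all():
                raise ValueError("spike counts must lie in 1..9")

    def roi_event_times(self, roi_id: str) -> np.ndarray:
        return self.events.loc[self.events["roi_id"] == roi_id, "time_s"].to_numpy()


# ---------------------------------------------------------------------------
# analytic moments (used for PC-noise calibration and in tests)

def amplitude_moments(params: SimParams, dist: np.ndarray | None = None) -> tuple[float, float]:
    """(E[a], E[a^2]) of event amplitudes under the burst distribution."""
    p = params.burst_dist if dist is None else np.asarray(dist, float)
    a = forward_amplitude(np.arange(1, 10), params.calibration)
    return float(np.sum(p * a)), float(np.sum(p * a**2))


def cf_signal_variance(params: SimParams) -> float:
    """Stationary variance of the noiseless CF trace (Campbell's theorem)."""
    _, ea2 = amplitude_moments(params)
    return params.rate_cf * ea2 * params.tau_decay / 2.0


def cf_trace_variance(params: SimParams) -> float:
    return cf_signal_variance(params) + params.noise_sd**2


def pc_noise_variance_matched(params: SimParams) -> float:
    """PC white-noise SD that equalizes CF and PC trace variances.

    With var(PC) = gain^2 var(signal) + sigma^2 = var(CF trace), the two channels'
    z-score (SD) units coincide and the configured gain is recovered by the
    amplitude-pair regression. This is the default calibration.
    """
    v = cf_signal_variance(params)
    s2 = cf_trace_variance(params) - params.pc_gain**2 * v
    return float(np.sqrt(max(s2, 1e-12)))


def pc_noise_for_target_correlation(params: SimParams, target_r: float) -> float:
    """PC white-noise SD giving trace correlation ``target_r`` for a pair.

    corr(CF, PC) = g V / (sd_cf * sd_pc) with V the shared signal variance;
    solving for the PC noise gives sigma^2 = (g V / (r sd_cf))^2 - g^2 V.
    """
    if not (0.0 < target_r < 1.0):
        raise ValueError("target correlation must lie in (0, 1)")
    v = cf_signal_variance(params)
    sd_cf = np.sqrt(cf_trace_variance(params))
    sd_pc_needed = params.pc_gain * v / (target_r * sd_cf)
    s2 = sd_pc_needed**2 - params.pc_gain**2 * v
    if s2 <= 0:
        raise ValueError("target correlation not reachable: shared drive too weak")
    return float(np.sqrt(s2))


def pc_noise_for_target_r2(params: SimParams, target_r2: float) -> float:
    """Amplitude-noise SD from the closed form sigma^2 = g^2 var(a) (1-R^2)/R^2."""
    if not (0.0 < target_r2 < 1.0):
        raise ValueError("target R^2 must lie in (0, 1)")
    ea, ea2 = amplitude_moments(params)
    var_a = ea2 - ea**2
    return float(params.pc_gain * np.sqrt(var_a * (1.0 - target_r2) / target_r2))


# ---------------------------------------------------------------------------
# trace rendering

def render_traces(
    events: pd.DataFrame,
    roi_ids: list[str],
    params: SimParams,
    amplitude_col: str = "amplitude",
) -> np.ndarray:
    """Render noiseless traces from a ground-truth event table.

    Each event deposits ``amplitude * exp(-(t_f - t_e)/tau)`` at the first frame
    ``t_f >= t_e`` and decays with the AR(1) factor thereafter; sub-frame rise
    time is collapsed (the indicator rise is far below one 31.25 ms frame).
    """
    n_frames = int(round(params.duration * params.fs_trace))
    impulses = np.zeros((len(roi_ids), n_frames))
    index = {r: i for i, r in enumerate(roi_ids)}
    fs, tau = params.fs_trace, params.tau_decay
    for roi, t, a in zip(events["roi_id"], events["time_s"], events[amplitude_col]):
        f = int(np.ceil(t * fs - 1e-9))
        if f >= n_frames:
            continue
        impulses[index[roi], f] += a * np.exp(-(f / fs - t) / tau)
    return lfilter([1.0], [1.0, -params.ar1_decay], impulses, axis=-1)


def _draw_counts(rng: np.random.Generator, dist: np.ndarray, size: int) -> np.ndarray:
    return rng.choice(np.arange(1, 10), size=size, p=dist)


def _place_rois(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    x = np.sort(rng.uniform(0.0, params.field_span_um, params.n_cf))
    y = rng.uniform(0.0, 30.0, params.n_cf)
    ids = [f"cf{i:03d}" for i in range(params.n_cf)]
    return make_roi_table(ids, x, y, radius_um=2.0, channel="CF")


# ---------------------------------------------------------------------------
# main generators

def simulate_cf_population(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[TraceMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a resting-state CF varicosity population.

    Population events arrive as a Poisson process at ``rate_cf``; each draws a
    seed ROI and every ROI joins with probability p(d) = sync_p0 exp(-d /
    sync_lambda) of its mediolateral distance d to the seed. Independent private
    events per ROI top the expected total rate up to exactly ``rate_cf``, so
    per-ROI event counts stay Poisson(rate_cf * duration). Spike counts are drawn
    per ROI per event from ``burst_dist``.
    """
    rng = params.rng() if rng is None else rng
    rois = _place_rois(params, rng)
    x = rois["x_um"].to_numpy()
    n = params.n_cf

    # expected shared-event rate per ROI, used to size the private top-up
    pmat = params.sync_p0 * np.exp(
        -np.abs(x[:, None] - x[None, :]) / params.sync_lambda
    )  # pmat[i, s]: participation prob of ROI i for a seed-s event
    lam_shared = params.rate_cf * pmat.mean(axis=1)
    lam_private = np.clip(params.rate_cf - lam_shared, 0.0, None)

    rows: list[dict] = []
    n_pop = rng.poisson(params.rate_cf * params.duration)
    pop_times = np.sort(rng.uniform(0.0, params.duration, n_pop))
    seeds = rng.integers(0, n, n_pop)
    for eid, (t, s) in enumerate(zip(pop_times, seeds)):
        joined = np.nonzero(rng.random(n) < pmat[:, s])[0]
        counts = _draw_counts(rng, params.burst_dist, joined.size)
        for i, c in zip(joined, counts):
            rows.append(
                {"roi_id": rois["roi_id"].iat[i], "time_s": t, "spike_count": int(c),
                 "pop_event_id": eid}
            )
    for i in range(n):
        k = rng.poisson(lam_private[i] * params.duration)
        times = rng.uniform(0.0, params.duration, k)
        counts = _draw_counts(rng, params.burst_dist, k)
        for t, c in zip(times, counts):
            rows.append(
                {"roi_id": rois["roi_id"].iat[i], "time_s": float(t),
                 "spike_count": int(c), "pop_event_id": -1}
            )

    events = pd.DataFrame(rows, columns=["roi_id", "time_s", "spike_count", "pop_event_id"])
    events["amplitude"] = forward_amplitude(
        events["spike_count"].to_numpy(), params.calibration
    ) if len(events) else []
    events["stim_evoked"] = False
    events["pressure"] = pd.Series([pd.NA] * len(events), dtype=object)
    events = events.sort_values(["roi_id", "time_s"], kind="stable").reset_index(drop=True)

    clean = render_traces(events, list(rois["roi_id"]), params)
    noisy = clean + rng.normal(0.0, params.noise_sd, clean.shape)
    trace = TraceMatrix(noisy, fs=params.fs_trace, units="raw-F", channel="CF",
                        roi_ids=list(rois["roi_id"]))
    return trace, rois, GroundTruth(events=events)


def simulate_paired_pc(
    cf_trace: TraceMatrix,
    cf_rois: pd.DataFrame,
    cf_truth: GroundTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[TraceMatrix, pd.DataFrame]:
    """Simulate PC dendrite traces paired to the first ``n_pc`` CF ROIs.

    Each paired PC receives the gain-scaled CF event train (same event times,
    amplitude ``pc_gain * a(n)``), plus independent non-CF events at
    ``non_cf_rate`` and white noise ``pc_noise_sd`` (default: variance-matched,
    see :func:`pc_noise_variance_matched`). PC centroids sit < 1 um from their CF.

    ``cf_truth`` is updated in place with ``pair_assignments`` and ``pc_events``.
    """
    rng = params.rng() if rng is None else rng
    n_pc = params.n_pc if params.n_pc > 0 else params.n_cf
    if n_pc > params.n_cf:
        raise ValueError("cannot pair more PCs than CFs")
    sigma = params.pc_noise_sd
    if sigma is None:
        sigma = pc_noise_variance_matched(params)

    cf_ids = list(cf_rois["roi_id"][:n_pc])
    pc_ids = [f"pc{i:03d}" for i in range(n_pc)]
    id_map = dict(zip(cf_ids, pc_ids))

    ev = cf_truth.events[cf_truth.events["roi_id"].isin(cf_ids)].copy()
    ev["roi_id"] = ev["roi_id"].map(id_map)
    ev["amplitude"] = params.pc_gain * ev["amplitude"]
    ev["source"] = "cf"

    ncf_rows = []
    if params.non_cf_rate > 0:
        for pid in pc_ids:
            k = rng.poisson(params.non_cf_rate * params.duration)
            times = rng.uniform(0.0, params.duration, k)
            counts = _draw_counts(rng, params.burst_dist, k)
            for t, c in zip(times, counts):
                ncf_rows.append(
                    {"roi_id": pid, "time_s": float(t), "spike_count": int(c),
                     "pop_event_id": -1,
                     "amplitude": forward_amplitude(int(c), params.calibration),
                     "stim_evoked": False, "pressure": pd.NA, "source": "non_cf"}
                )
    pc_events = pd.concat([ev, pd.DataFrame(ncf_rows, columns=list(ev.columns))],
                          ignore_index=True) if ncf_rows else ev
    pc_events = pc_events.sort_values(["roi_id", "time_s"], kind="stable").reset_index(drop=True)

    clean = render_traces(pc_events, pc_ids, params)
    noisy = clean + rng.normal(0.0, sigma, clean.shape)
    pc_trace = TraceMatrix(noisy, fs=params.fs_trace, units="raw-F", channel="PC",
                           roi_ids=pc_ids)

    # paired PC centroid within 1 um of its CF
    off = rng.uniform(-0.3, 0.3, (n_pc, 2))
    pc_rois = make_roi_table(
        pc_ids,
        cf_rois["x_um"].to_numpy()[:n_pc] + off[:, 0],
        cf_rois["y_um"].to_numpy()[:n_pc] + off[:, 1],
        radius_um=2.0,
        channel="PC",
    )
    cf_truth.pair_assignments = pd.DataFrame(
        {"cf_id": cf_ids, "pc_id": pc_ids, "gain": params.pc_gain}
    )
    cf_truth.pc_events = pc_events
    return pc_trace, pc_rois


def _check_dominance(p_low: np.ndarray, p_high: np.ndarray) -> None:
    # stochastic dominance: CDF of the stronger stimulus never exceeds the weaker
    if np.any(np.cumsum(p_high) > np.cumsum(p_low) + 1e-9):
        raise ValueError("intensity_map must make P2 stochastically >= P1")


def simulate_stimulus_session(
    params: SimParams,
    stim: StimulusLog,
    intensity_map: Mapping[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TraceMatrix, pd.DataFrame, GroundTruth]:
    """Simulate an air-puff session: spontaneous background plus evoked events.

    After each puff every ROI fires one evoked event at latency ~
    N(evoked_latency_ms, evoked_jitter_ms), clipped to (5 ms, 290 ms), with spike
    count drawn from the pressure level's burst distribution.
    """
    rng = params.rng() if rng is None else rng
    imap = {k: np.asarray(v, float) for k, v in (intensity_map or default_intensity_map()).items()}
    for lbl in set(stim.pressures):
        if lbl not in imap:
            raise ValueError(f"intensity_map missing pressure level {lbl}")
        v = imap[lbl]
        if v.shape != (9,) or abs(v.sum() - 1.0) > 1e-9 or np.any(v < 0):
            raise ValueError("intensity_map entries must be probability vectors over 1..9")
    if "P1" in imap and "P2" in imap:
        _check_dominance(imap["P1"], imap["P2"])
    if stim.puff_times.size and (
        stim.puff_times.min() < 0 or stim.puff_times.max() >= params.duration
    ):
        raise ValueError("puff times must lie inside [0, duration)")

    trace, rois, truth = simulate_cf_population(params, rng)
    ev_rows = []
    for t, lbl in zip(stim.puff_times, stim.pressures):
        lat = np.clip(
            rng.normal(params.evoked_latency_ms, params.evoked_jitter_ms, params.n_cf),
            5.0, 290.0,
        ) / 1000.0
        counts = _draw_counts(rng, imap[lbl], params.n_cf)
        for i in range(params.n_cf):
            te = t + lat[i]
            if te >= params.duration:
                continue
            ev_rows.append(
                {"roi_id": rois["roi_id"].iat[i], "time_s": float(te),
                 "spike_count": int(counts[i]), "pop_event_id": -1,
                 "amplitude": forward_amplitude(int(counts[i]), params.calibration),
                 "stim_evoked": True, "pressure": lbl}
            )
    evoked = pd.DataFrame(ev_rows, columns=list(truth.events.columns))
    events = pd.concat([truth.events, evoked], ignore_index=True)
    events = events.sort_values(["roi_id", "time_s"], kind="stable").reset_index(drop=True)

    clean = render_traces(events, list(rois["roi_id"]), params)
    noisy = clean + rng.normal(0.0, params.noise_sd, clean.shape)
    trace = TraceMatrix(noisy, fs=params.fs_trace, units="raw-F", channel="CF",
                        roi_ids=list(rois["roi_id"]))
    return trace, rois, GroundTruth(events=events)


def _twitch(t: np.ndarray, onset: float, peak: float, amp: float, decay_s: float) -> np.ndarray:
    """Single-peaked twitch waveform: half-cosine rise then half-cosine decay."""
    v = np.zeros_like(t)
    rise = (t >= onset) & (t <= peak)
    v[rise] = amp * np.sin(0.5 * np.pi * (t[rise] - onset) / (peak - onset)) ** 2
    fall = (t > peak) & (t <= peak + decay_s)
    v[fall] = amp * np.cos(0.5 * np.pi * (t[fall] - peak) / decay_s) ** 2
    return v


def simulate_motion(
    stim: StimulusLog,
    params: SimParams,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
) -> tuple[MotionTrace, pd.DataFrame]:
    """Simulate the forepaw-speed trace for an air-puff session.

    Each puff triggers a twitch whose onset lags the puff by a draw centred on
    23.2 ms (SD 2.9 ms) and whose peak lags by a draw centred on 57.6 ms (SD
    5.8 ms); the peak speed is drawn independently of any CF amplitude (the
    motion-null regime, R^2 < 0.001). Baseline is rectified white noise.

    Returns the trace and a per-trial truth table (true latencies, peak speeds).
    """
    rng = params.rng() if rng is None else rng
    if duration is None:
        duration = (stim.puff_times.max() + 2.0) if stim.puff_times.size else params.duration
    n = int(round(duration * params.fs_motion))
    t = np.arange(n) / params.fs_motion
    speed = np.abs(rng.normal(0.0, params.motion_baseline_sd, n)) if params.motion_baseline_sd > 0 else np.zeros(n)

    rows = []
    for tp in stim.puff_times:
        onset_lat = rng.normal(params.motion_onset_ms, params.motion_onset_jitter_ms) / 1000.0
        peak_lat = rng.normal(params.motion_peak_ms, params.motion_peak_jitter_ms) / 1000.0
        peak_lat = max(peak_lat, onset_lat + 0.005)
        amp = max(rng.normal(params.twitch_peak_mean, params.twitch_peak_sd), 5.0)
        speed += _twitch(t, tp + onset_lat, tp + peak_lat, amp, params.twitch_decay_ms / 1000.0)
        rows.append(
            {"puff_time_s": float(tp), "onset_latency_ms": onset_lat * 1000.0,
             "peak_latency_ms": peak_lat * 1000.0, "peak_speed": amp}
        )
    truth = pd.DataFrame(rows, columns=["puff_time_s", "onset_latency_ms",
                                        "peak_latency_ms", "peak_speed"])
    return MotionTrace(speed, fs=params.fs_motion), truth
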