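import dataclasses

import numpy as np
import pandas as pd
import pytest

from cfpc import SimParams, simulate_cf_population, simulate_motion, simulate_paired_pc
from cfpc.burst import forward_amplitude
from cfpc.containers import StimulusLog
from cfpc.simulate import (amplitude_moments, cf_signal_variance,
                           cf_trace_variance, default_burst_dist,
                           default_intensity_map, pc_noise_for_target_correlation,
                           pc_noise_for_target_r2, pc_noise_variance_matched,
                           render_traces, simulate_stimulus_session)


class TestParams:
    def test_burst_dist_default_valid(self):
        p = default_burst_dist()
        assert p.shape == (9,)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p[7:] == 0)

    def test_rejects_bad_burst_dist(self):
        bad = np.ones(9)
        with pytest.raises(ValueError, match="probability vector"):
            SimParams(burst_dist=bad)

    @pytest.mark.parametrize(
        "kwargs", [dict(rate_cf=0.0), dict(duration=0.0), dict(tau_decay=-1.0),
                   dict(sync_p0=1.5), dict(n_pc=5, n_cf=3), dict(pc_gain=0.0),
                   dict(noise_sd=-0.1)]
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)

    def test_ar1_decay(self):
        p = SimParams()
        assert p.ar1_decay == pytest.approx(np.exp(-1.0 / (32.0 * 0.4)))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = SimParams(seed=7, n_cf=4, duration=30.0)
        t1, r1, g1 = simulate_cf_population(p)
        t2, r2, g2 = simulate_cf_population(p)
        assert np.array_equal(t1.values, t2.values)
        pd.testing.assert_frame_equal(g1.events, g2.events)
        pd.testing.assert_frame_equal(r1, r2)

    def test_different_seed_differs(self):
        t1, _, _ = simulate_cf_population(SimParams(seed=1, n_cf=2, duration=30.0))
        t2, _, _ = simulate_cf_population(SimParams(seed=2, n_cf=2, duration=30.0))
        assert not np.array_equal(t1.values, t2.values)

    def test_motion_deterministic(self):
        p = SimParams(seed=3)
        stim = StimulusLog.regular(5)
        m1, tr1 = simulate_motion(stim, p)
        m2, tr2 = simulate_motion(stim, p)
        assert np.array_equal(m1.speed, m2.speed)
        pd.testing.assert_frame_equal(tr1, tr2)


class TestEventStatistics:
    def test_poisson_count_recovery(self):
        # 30 ROIs x 600 s at 0.85 Hz: mean per-ROI count within 3 Poisson SDs
        p = SimParams(seed=11, n_cf=30, duration=600.0)
        _, _, truth = simulate_cf_population(p)
        per_roi = truth.events.groupby("roi_id").size().to_numpy()
        expected = 0.85 * 600.0
        # population events are shared across ROIs, so the SD of the mean of 30
        # correlated counts is bounded by the single-ROI Poisson SD
        assert abs(per_roi.mean() - expected) < 3 * np.sqrt(expected)

    def test_sync_lambda_zero_gives_independent_trains(self):
        p = SimParams(seed=5, n_cf=6, duration=400.0, sync_lambda=1e-9, sync_p0=0.0)
        _, _, truth = simulate_cf_population(p)
        # bin ground-truth event counts and correlate across ROIs
        edges = np.arange(0.0, 400.0 + 0.5, 0.5)
        counts = np.vstack([
            np.histogram(truth.roi_event_times(f"cf{i:03d}"), bins=edges)[0]
            for i in range(6)
        ])
        c = np.corrcoef(counts)
        off = c[~np.eye(6, dtype=bool)]
        # independent Poisson trains: |r| ~ 1/sqrt(n_bins) = 0.035
        assert np.all(np.abs(off) < 0.12)

    def test_synchrony_creates_shared_events(self):
        p = SimParams(seed=5, n_cf=6, duration=200.0)
        _, _, truth = simulate_cf_population(p)
        shared = truth.events[truth.events["pop_event_id"] >= 0]
        multi = shared.groupby("pop_event_id").size()
        assert (multi >= 2).any()

    def test_event_times_in_range(self, small_session):
        _, _, truth = small_session
        assert (truth.events["time_s"] >= 0).all()
        assert (truth.events["time_s"] < 120.0).all()
        assert truth.events["spike_count"].between(1, 9).all()


class TestAmplitudeModel:
    def test_saturation(self):
        p = SimParams()
        a = forward_amplitude(np.arange(1, 10), p.calibration)
        assert np.all(np.diff(a) > 0)
        assert a[6] / p.a_max == pytest.approx(1 - np.exp(-7 / 2.0), abs=1e-12)
        assert np.all(a < p.a_max)

    def test_moments_match_manual(self):
        p = SimParams()
        ea, ea2 = amplitude_moments(p)
        a = forward_amplitude(np.arange(1, 10), p.calibration)
        assert ea == pytest.approx(np.sum(p.burst_dist * a))
        assert ea2 == pytest.approx(np.sum(p.burst_dist * a**2))

    def test_campbell_variance_matches_simulation(self):
        # long noiseless simulation: trace variance ~ rate * E[a^2] * tau / 2
        p = SimParams(seed=2, n_cf=12, duration=900.0, noise_sd=0.0,
                      sync_p0=0.0)
        trace, _, _ = simulate_cf_population(p)
        v_emp = trace.values.var(axis=1).mean()
        v_th = cf_signal_variance(p)
        assert v_emp == pytest.approx(v_th, rel=0.12)

    def test_trace_variance_adds_noise(self):
        p = SimParams()
        assert cf_trace_variance(p) == pytest.approx(
            cf_signal_variance(p) + p.noise_sd**2
        )


class TestRenderTraces:
    def test_single_event_peak_and_decay(self):
        p = SimParams(n_cf=1, duration=4.0, noise_sd=0.0)
        ev = pd.DataFrame(
            {"roi_id": ["r0"], "time_s": [1.0], "amplitude": [2.5]}
        )
        out = render_traces(ev, ["r0"], p)
        f = int(np.ceil(1.0 * 32.0))
        assert out[0, f] == pytest.approx(2.5)
        assert out[0, f + 1] == pytest.approx(2.5 * p.ar1_decay)
        assert np.all(out[0, :f] == 0)

    def test_subframe_event_partial_decay(self):
        p = SimParams(n_cf=1, duration=4.0, noise_sd=0.0)
        t0 = 1.0 + 0.4 / 32.0  # 0.4 frames past a frame boundary
        ev = pd.DataFrame({"roi_id": ["r0"], "time_s": [t0], "amplitude": [1.0]})
        out = render_traces(ev, ["r0"], p)
        f = int(np.ceil(t0 * 32.0 - 1e-9))
        assert out[0, f] == pytest.approx(np.exp(-(f / 32.0 - t0) / 0.4))


class TestPairedPC:
    def test_pair_geometry_and_truth(self):
        p = SimParams(seed=4, n_cf=5, n_pc=5, duration=60.0)
        cf_trace, cf_rois, truth = simulate_cf_population(p)
        pc_trace, pc_rois = simulate_paired_pc(cf_trace, cf_rois, truth, p)
        assert pc_trace.n_rois == 5
        d = np.hypot(cf_rois["x_um"].to_numpy() - pc_rois["x_um"].to_numpy(),
                     cf_rois["y_um"].to_numpy() - pc_rois["y_um"].to_numpy())
        assert np.all(d < 1.0)
        assert list(truth.pair_assignments["gain"]) == [0.61] * 5
        assert truth.pc_events is not None

    def test_paired_trace_correlated_with_cf(self):
        p = SimParams(seed=4, n_cf=3, n_pc=3, duration=120.0)
        cf_trace, cf_rois, truth = simulate_cf_population(p)
        pc_trace, _ = simulate_paired_pc(cf_trace, cf_rois, truth, p)
        r = np.corrcoef(cf_trace.values[0], pc_trace.values[0])[0, 1]
        assert r > 0.3

    def test_noise_calibrations(self):
        p = SimParams()
        s_match = pc_noise_variance_matched(p)
        v = cf_signal_variance(p)
        assert s_match**2 + p.pc_gain**2 * v == pytest.approx(cf_trace_variance(p))
        s_r = pc_noise_for_target_correlation(p, 0.605)
        sd_pc = np.sqrt(p.pc_gain**2 * v + s_r**2)
        r = p.pc_gain * v / (np.sqrt(cf_trace_variance(p)) * sd_pc)
        assert r == pytest.approx(0.605, abs=1e-9)
        ea, ea2 = amplitude_moments(p)
        var_a = ea2 - ea**2
        s2 = pc_noise_for_target_r2(p, 0.48)
        assert s2**2 == pytest.approx(p.pc_gain**2 * var_a * 0.52 / 0.48)

    def test_calibration_input_validation(self):
        p = SimParams()
        with pytest.raises(ValueError):
            pc_noise_for_target_correlation(p, 1.5)
        with pytest.raises(ValueError):
            pc_noise_for_target_r2(p, 0.0)


class TestStimulusSession:
    def test_evoked_events_flagged(self):
        p = SimParams(seed=6, n_cf=4, duration=30.0)
        stim = StimulusLog.regular(4)
        _, _, truth = simulate_stimulus_session(p, stim)
        ev = truth.events[truth.events["stim_evoked"]]
        assert len(ev) > 0
        assert set(ev["pressure"].unique()) <= {"P1", "P2"}
        # each evoked event trails its puff by < 300 ms
        lat = ev["time_s"].to_numpy()[:, None] - stim.puff_times[None, :]
        lat[lat < 0] = np.inf
        assert np.all(lat.min(axis=1) < 0.3)

    def test_puff_outside_duration_rejected(self):
        p = SimParams(n_cf=2, duration=5.0)
        with pytest.raises(ValueError, match="inside"):
            simulate_stimulus_session(p, StimulusLog.regular(3))

    def test_dominance_enforced(self):
        p = SimParams(seed=6, n_cf=2, duration=30.0)
        stim = StimulusLog.regular(2, pressure=["P1", "P2"])
        imap = default_intensity_map()
        bad = {"P1": imap["P2"], "P2": imap["P1"]}  # swapped: P2 weaker
        with pytest.raises(ValueError, match="stochastically"):
            simulate_stimulus_session(p, stim, intensity_map=bad)


class TestMotion:
    def test_truth_columns_and_nonnegative_speed(self):
        p = SimParams(seed=2)
        m, truth = simulate_motion(StimulusLog.regular(10), p)
        assert list(truth.columns) == ["puff_time_s", "onset_latency_ms",
                                       "peak_latency_ms", "peak_speed"]
        assert np.all(m.speed >= 0)
        assert m.fs == 64.0

    def test_latency_distribution(self):
        p = SimParams(seed=8)
        _, truth = simulate_motion(StimulusLog.regular(200), p)
        assert truth["onset_latency_ms"].mean() == pytest.approx(23.2, abs=1.0)
        assert truth["peak_latency_ms"].mean() == pytest.approx(57.6, abs=2.0)
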