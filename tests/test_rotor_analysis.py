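"""Phase-singularity detection, period measurement, outcome classification."""

import numpy as np
import pytest

from rotoranchor import analysis
from rotoranchor.analysis import (OutcomeRecord, PHASE_TAU_MS,
                                  detect_singularities, measure_period,
                                  classify, time_to_anchor)
from rotoranchor.scar import ScarSpec
from rotoranchor.tissue import SimRecording


V_STAR = analysis.V_STAR_MV


def brute_force_winding(frame_now, frame_prev, v_star=V_STAR):
    """Independent plaquette-by-plaquette winding computation (loops)."""
    theta = np.arctan2(frame_now - v_star, frame_prev - v_star)
    hits = []
    rows, cols = theta.shape
    for r in range(rows - 1):
        for c in range(cols - 1):
            corners = [theta[r, c], theta[r, c + 1],
                       theta[r + 1, c + 1], theta[r + 1, c]]
            if any(np.isnan(x) for x in corners):
                continue
            w = 0.0
            for k in range(4):
                d = corners[(k + 1) % 4] - corners[k]
                while d > np.pi:
                    d -= 2 * np.pi
                while d <= -np.pi:
                    d += 2 * np.pi
                w += d
            if abs(w) > np.pi:
                hits.append((r + 0.5, c + 0.5, int(np.sign(w))))
    return hits


def spiral_frames(shape=(40, 40), center=(20.5, 19.5), chirality=1, turns=1.0):
    """Analytic Archimedean-spiral phase field rendered into two V frames
    such that atan2(now - V*, prev - V*) reproduces the phase exactly."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    ang = np.arctan2(rr - center[0], cc - center[1])
    rad = np.hypot(rr - center[0], cc - center[1])
    theta = chirality * ang + 2 * np.pi * turns * rad / max(shape)
    now = V_STAR + 30.0 * np.sin(theta)
    prev = V_STAR + 30.0 * np.cos(theta)
    return now, prev


class TestDetector:
    def test_uniform_resting_tissue_has_no_singularity(self):
        f = np.full((30, 30), -85.0)
        assert detect_singularities(f, f) == []

    @pytest.mark.parametrize("chirality", [1, -1])
    def test_single_spiral_core(self, chirality):
        now, prev = spiral_frames(chirality=chirality)
        sings = detect_singularities(now, prev)
        assert len(sings) == 1
        s = sings[0]
        assert abs(s.row - 20.5) <= 1.0 and abs(s.col - 19.5) <= 1.0
        assert s.charge == chirality

    def test_figure_eight_has_net_charge_zero(self):
        """Smooth field with two mirrored cores: phase = ang(c1) - ang(c2)
        winds +2pi around one core and -2pi around the other."""
        rr, cc = np.meshgrid(np.arange(40), np.arange(80), indexing="ij")
        a1 = np.arctan2(rr - 20.5, cc - 20.5)
        a2 = np.arctan2(rr - 20.5, cc - 60.5)
        theta = a1 - a2
        now = V_STAR + 30.0 * np.sin(theta)
        prev = V_STAR + 30.0 * np.cos(theta)
        sings = detect_singularities(now, prev)
        assert len(sings) == 2
        assert sum(s.charge for s in sings) == 0
        assert {s.charge for s in sings} == {-1, 1}

    def test_equals_brute_force_on_random_smooth_fields(self, rng):
        for _ in range(5):
            a = rng.standard_normal((12, 12))
            b = rng.standard_normal((12, 12))
            # smooth them so phase is well defined away from grid noise
            from scipy.ndimage import gaussian_filter
            now = V_STAR + 25 * gaussian_filter(a, 1.5)
            prev = V_STAR + 25 * gaussian_filter(b, 1.5)
            got = {(s.row, s.col, s.charge)
                   for s in detect_singularities(now, prev)}
            want = set(brute_force_winding(now, prev))
            assert got == want

    def test_obstacle_plaquettes_are_skipped(self):
        now, prev = spiral_frames()
        now[19:22, 18:21] = np.nan
        prev[19:22, 18:21] = np.nan
        got = {(s.row, s.col, s.charge)
               for s in detect_singularities(now, prev)}
        want = set(brute_force_winding(now, prev))
        assert got == want    # detector and oracle skip the same plaquettes

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            detect_singularities(np.zeros((4, 4)), np.zeros((5, 4)))


def pulse_train_probe(period_ms, t_end=2000.0, dt=1.0, phase=0.0,
                      width=120.0):
    """Synthetic probe trace: square action-potential-like pulses."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    v = np.full_like(t, -80.0)
    start = phase
    while start < t_end:
        v[(t >= start) & (t < start + width)] = 10.0
        start += period_ms
    return t, v


class TestPeriod:
    @pytest.mark.parametrize("period", [300.0, 222.0])
    def test_pulse_train_period(self, period):
        t, v = pulse_train_probe(period)
        traces = np.stack([pulse_train_probe(period, phase=ph)[1]
                           for ph in (0.0, 40.0, 90.0)])
        got = measure_period(t, traces, window_end=1990.0, window=640.0)
        assert got == pytest.approx(period, abs=1.0)

    def test_quiescent_trace_is_window_censored(self):
        t = np.arange(0.0, 1000.0)
        v = np.full((2, t.size), -80.0)
        got = measure_period(t, v, window_end=990.0, window=320.0)
        assert got == 320.0

    def test_anchored_like_period_exceeds_threshold_in_320ms_window(self):
        t, _ = pulse_train_probe(307.0)
        traces = np.stack([pulse_train_probe(307.0, phase=ph)[1]
                           for ph in (0.0, 100.0, 200.0)])
        got = measure_period(t, traces, window_end=1990.0, window=320.0)
        assert got > 280.0

    def test_free_rotor_period_resolved_in_320ms_window(self):
        traces = np.stack([pulse_train_probe(222.0, phase=ph, width=80.0)[1]
                           for ph in (0.0, 50.0, 120.0, 180.0)])
        t = np.arange(0.0, 2001.0)
        got = measure_period(t, traces, window_end=1990.0, window=320.0)
        assert got == pytest.approx(222.0, abs=1.0)


def synthetic_recording(probe_traces, probe_t, final_frame,
                        frames=None, frame_times=None):
    frames = frames if frames is not None else np.stack([final_frame] * 3)
    frame_times = (frame_times if frame_times is not None
                   else np.array([probe_t[0],
                                  probe_t[-1] - PHASE_TAU_MS, probe_t[-1]]))
    return SimRecording(frame_times=frame_times, frames=frames,
                        probe_t=probe_t, probe_v=probe_traces,
                        probe_rc=np.zeros((probe_traces.shape[0], 2), int))


class TestClassify:
    def test_all_subthreshold_is_terminated(self):
        t = np.arange(0.0, 2001.0)
        traces = np.full((3, t.size), -80.0)
        quiet = np.full((20, 20), -82.0)
        rec = synthetic_recording(traces, t, quiet)
        out = classify(rec)
        assert out.label == "terminated"

    def test_slow_pattern_is_anchored(self):
        t = np.arange(0.0, 2001.0)
        traces = np.stack([pulse_train_probe(300.0, phase=ph)[1]
                           for ph in (0.0, 50.0, 150.0)])
        frame = np.full((20, 20), -80.0)
        frame[5:9, 5:9] = 0.0   # active region at classification time
        rec = synthetic_recording(traces, t, frame)
        out = classify(rec)
        assert out.anchored
        assert out.period_ms > 280.0

    def test_fast_pattern_is_not_anchored(self):
        t = np.arange(0.0, 2001.0)
        traces = np.stack([pulse_train_probe(222.0, phase=ph, width=80.0)[1]
                           for ph in (0.0, 60.0, 120.0, 170.0)])
        frame = np.full((20, 20), -80.0)
        frame[3:7, 3:7] = 5.0
        rec = synthetic_recording(traces, t, frame)
        out = classify(rec)
        assert out.label == "not_anchored"

    def test_recording_shorter_than_classification_time_rejected(self):
        t = np.arange(0.0, 501.0)
        traces = np.full((2, t.size), -80.0)
        rec = synthetic_recording(traces, t, np.full((8, 8), -80.0))
        with pytest.raises(ValueError, match="before"):
            classify(rec, classification_time=2000.0)

    def test_anchored_arm_count_from_rim_singularities(self):
        """Two same-sign spiral cores near the scar rim -> two-armed."""
        t = np.arange(0.0, 2001.0)
        traces = np.stack([pulse_train_probe(310.0, phase=ph)[1]
                           for ph in (0.0, 100.0)])
        sspec = ScarSpec(center=(30, 30), diameter=1.0, profile="uniform",
                         level=30.0)
        now1, prev1 = spiral_frames(shape=(60, 60), center=(30.5, 10.5))
        now2, prev2 = spiral_frames(shape=(60, 60), center=(30.5, 50.5))
        # superpose two far-apart cores by stitching half-planes
        now = np.where(np.arange(60)[None, :] < 30, now1, now2)
        prev = np.where(np.arange(60)[None, :] < 30, prev1, prev2)
        # rim at r = 0.5 cm (20 nodes): move cores onto the annulus
        frames = np.stack([now, prev, now])
        frame_times = np.array([0.0, t[-1] - PHASE_TAU_MS, t[-1]])
        rec = synthetic_recording(traces, t, now, frames=frames,
                                  frame_times=frame_times)
        out = classify(rec, sspec)
        assert out.anchored
        assert out.n_arms == 2
        assert out.label == "anchored_multi"


class TestTimeToAnchor:
    def _recording_with_transition(self, t_switch_ms, t_end=8000.0,
                                   before=222.0, after=300.0):
        t = np.arange(0.0, t_end + 1.0)
        traces = []
        for ph in (0.0, 60.0, 130.0):
            _, v1 = pulse_train_probe(before, t_end=t_switch_ms, phase=ph,
                                      width=80.0)
            _, v2 = pulse_train_probe(after, t_end=t_end - t_switch_ms,
                                      phase=ph)
            traces.append(np.concatenate([v1[:-1], v2]))
        traces = np.stack(traces)[:, :t.size]
        frame = np.full((10, 10), -80.0)
        frame[4, 4] = 0.0
        return synthetic_recording(traces, t, frame)

    def test_transition_time_recovered(self):
        rec = self._recording_with_transition(5000.0)
        out = classify(rec)
        assert out.anchored
        assert out.time_to_event_s == pytest.approx(5.0, abs=0.5)

    def test_immediate_anchoring_reports_near_zero(self):
        rec = self._recording_with_transition(0.0)
        out = classify(rec)
        assert out.time_to_event_s <= 0.5

    def test_transient_excursion_is_ignored(self):
        """A brief slow interlude early in an otherwise fast pattern must not
        count: the reported time reflects the *final* persistent change."""
        t = np.arange(0.0, 9001.0)
        traces = []
        for ph in (0.0, 60.0, 130.0):
            _, fast1 = pulse_train_probe(222.0, t_end=3000.0, phase=ph,
                                         width=80.0)
            _, slow_blip = pulse_train_probe(320.0, t_end=1000.0, phase=ph)
            _, fast2 = pulse_train_probe(222.0, t_end=2000.0, phase=ph,
                                         width=80.0)
            _, slow = pulse_train_probe(300.0, t_end=3000.0, phase=ph)
            traces.append(np.concatenate([fast1[:-1], slow_blip[:-1],
                                          fast2[:-1], slow])[:t.size])
        frame = np.full((10, 10), -80.0)
        frame[4, 4] = 0.0
        rec = synthetic_recording(np.stack(traces), t, frame)
        out = classify(rec)
        assert out.anchored
        assert out.time_to_event_s >= 5.5

    def test_not_anchored_is_undefined(self):
        t = np.arange(0.0, 2001.0)
        traces = np.stack([pulse_train_probe(222.0, phase=ph, width=80.0)[1]
                           for ph in (0.0, 60.0, 120.0)])
        frame = np.full((10, 10), -80.0)
        frame[4, 4] = 0.0
        rec = synthetic_recording(traces, t, frame)
        with pytest.raises(ValueError, match="undefined"):
            time_to_anchor(rec)

    def test_terminated_reports_last_suprathreshold_frame(self):
        t = np.arange(0.0, 3001.0)
        traces = np.full((2, t.size), -80.0)
        active = np.full((10, 10), -80.0)
        active[3, 3] = 0.0
        quiet = np.full((10, 10), -80.0)
        frames = np.stack([active, active, quiet, quiet])
        frame_times = np.array([0.0, 1200.0, 2400.0, 3000.0])
        rec = synthetic_recording(traces, t, quiet, frames=frames,
                                  frame_times=frame_times)
        out = classify(rec)
        assert out.label == "terminated"
        assert out.time_to_event_s == pytest.approx(1.2, abs=0.01)
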