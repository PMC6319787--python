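"""Phase-singularity detection, period measurement and outcome classification.

A rotor's organizing center is located as a phase singularity: with the
time-delay phase

    theta(x, t) = atan2(V(x, t) - V*, V(x, t - tau) - V*)

(tau = 20 ms, V* = -40 mV by default), the winding number of theta around an
elementary grid plaquette is +-2*pi exactly at a spiral core and 0 elsewhere.
The topological charge (+1 counter-clockwise, -1 clockwise, in grid
coordinates with row index increasing downward) is the winding sign.

Outcome classification follows the study's operational rules: a run is
*terminated* when every myocyte is below -20 mV at the classification time;
otherwise it is *anchored* when the period of the excitation pattern exceeds
280 ms over a 320 ms measuring window (an anchored scar rotor turns at
~300 ms, a free rotor at ~220 ms); otherwise *not anchored*.  Arm count and
chirality of anchored rotors come from the singularities found within 1 cm
of the scar rim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .scar import ScarSpec
from .tissue import DX_CM, SimRecording

__all__ = ["PhaseSingularity", "OutcomeRecord", "PHASE_TAU_MS", "V_STAR_MV",
           "phase_field", "detect_singularities", "measure_period",
           "classify", "time_to_anchor", "singularity_track",
           "tip_displacement"]

PHASE_TAU_MS = 20.0
V_STAR_MV = -40.0
ACTIVATION_LEVEL_MV = -20.0
PERIOD_THRESHOLD_MS = 280.0
PERIOD_WINDOW_MS = 320.0
ANNULUS_CM = 1.0


@dataclass(frozen=True)
class PhaseSingularity:
    """One phase singularity: plaquette-center position and winding sign."""

    row: float
    col: float
    charge: int
    t: float = float("nan")

    def position_cm(self, dx: float = DX_CM) -> Tuple[float, float]:
        return (self.row * dx, self.col * dx)


@dataclass
class OutcomeRecord:
    """Classification of one simulation run."""

    label: str                      # terminated | anchored_single_cw |
    #                                 anchored_single_ccw | anchored_multi |
    #                                 not_anchored
    period_ms: float
    classification_time_ms: float
    n_arms: int = 0
    chirality: int = 0              # +1 CCW, -1 CW, 0 n/a
    time_to_event_s: float = float("nan")
    seed: int = 0
    config_hash: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def anchored(self) -> bool:
        return self.label.startswith("anchored")

    def row(self) -> dict:
        return {"label": self.label, "period_ms": self.period_ms,
                "t_classify_ms": self.classification_time_ms,
                "n_arms": self.n_arms, "chirality": self.chirality,
                "time_to_event_s": self.time_to_event_s, "seed": self.seed,
                "config_hash": self.config_hash, **self.extra}


def phase_field(frame_now: np.ndarray, frame_delay: np.ndarray,
                v_star: float = V_STAR_MV) -> np.ndarray:
    """Time-delay embedding phase; NaN where either frame is NaN (obstacle)."""
    if frame_now.shape != frame_delay.shape:
        raise ValueError("frames have mismatched shapes")
    return np.arctan2(frame_now - v_star, frame_delay - v_star)


def _wrap(dphi: np.ndarray) -> np.ndarray:
    return (dphi + np.pi) % (2.0 * np.pi) - np.pi


def detect_singularities(frame_now: np.ndarray, frame_delay: np.ndarray,
                         v_star: float = V_STAR_MV,
                         t: float = float("nan")) -> List[PhaseSingularity]:
    """Phase singularities of the frame pair, by plaquette winding number.

    For every 2x2 plaquette the wrapped phase differences are summed around
    the loop (counter-clockwise in grid coordinates); a total of +-2*pi marks
    a singularity at the plaquette center.  Plaquettes touching an obstacle
    or boundary NaN are skipped — the phase is undefined there.
    """
    theta = phase_field(frame_now, frame_delay, v_star)
    a = theta[:-1, :-1]
    b = theta[:-1, 1:]
    c = theta[1:, 1:]
    d = theta[1:, :-1]
    winding = _wrap(b - a) + _wrap(c - b) + _wrap(d - c) + _wrap(a - d)
    valid = np.isfinite(winding)
    hits = valid & (np.abs(winding) > np.pi)
    rows, cols = np.nonzero(hits)
    return [PhaseSingularity(row=r + 0.5, col=c_ + 0.5,
                             charge=int(np.sign(winding[r, c_])), t=t)
            for r, c_ in zip(rows, cols)]


def measure_period(probe_t: np.ndarray, probe_v: np.ndarray,
                   window_end: float, window: float = PERIOD_WINDOW_MS,
                   threshold: float = ACTIVATION_LEVEL_MV) -> float:
    """Period of the excitation pattern over a measuring window (ms).

    Activation times are -20 mV upward crossings of each probe trace inside
    ``[window_end - window, window_end]``.  The period is the median of all
    observed inter-activation intervals pooled across probes; when no probe
    activates twice inside the window the period is right-censored at the
    window length (reported as the window length itself, i.e. "longer than
    the window").
    """
    if probe_v.size == 0:
        raise ValueError("no probe traces recorded")
    t0 = window_end - window
    sel = (probe_t >= t0 - 1e-9) & (probe_t <= window_end + 1e-9)
    ts = probe_t[sel]
    if ts.size < 3:
        raise ValueError("probe sampling does not cover the measuring window")
    intervals: List[float] = []
    for tr in probe_v[:, sel]:
        k = np.flatnonzero((tr[1:] >= threshold) & (tr[:-1] < threshold))
        if k.size >= 2:
            cross = ts[k] + (ts[k + 1] - ts[k]) * (threshold - tr[k]) / (tr[k + 1] - tr[k])
            intervals.extend(np.diff(cross).tolist())
    if not intervals:
        return float(window)
    return float(np.median(intervals))


def _rim_distance_grid(shape, spec: ScarSpec, dx: float) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    r = np.hypot(rr - spec.center[0], cc - spec.center[1]) * dx
    return np.abs(r - spec.radius_cm)


def classify(recording: SimRecording, scar_spec: Optional[ScarSpec] = None,
             classification_time: Optional[float] = None,
             period_threshold: float = PERIOD_THRESHOLD_MS,
             window: float = PERIOD_WINDOW_MS,
             tau: float = PHASE_TAU_MS) -> OutcomeRecord:
    """Classify a run as terminated / anchored / not anchored.

    ``classification_time`` defaults to the end of the recording (the study
    protocol applies the rule at a fixed late time, 40 s at full scale).
    Requires the recording to span the classification time and the measuring
    window before it.
    """
    t_c = (recording.probe_t[-1] if classification_time is None
           else float(classification_time))
    if recording.probe_t[-1] + 1e-6 < t_c:
        raise ValueError(
            f"recording ends at {recording.probe_t[-1]:.0f} ms, before the "
            f"classification time {t_c:.0f} ms")

    frame = recording.frame_at(t_c)
    myo = np.isfinite(frame)
    if bool((frame[myo] < ACTIVATION_LEVEL_MV).all()):
        rec_out = OutcomeRecord(label="terminated", period_ms=float("nan"),
                                classification_time_ms=t_c,
                                seed=recording.seed,
                                config_hash=recording.config_hash)
        rec_out.time_to_event_s = time_to_anchor(recording, scar_spec,
                                                 outcome=rec_out)
        return rec_out

    period = measure_period(recording.probe_t, recording.probe_v, t_c, window)
    if period <= period_threshold:
        return OutcomeRecord(label="not_anchored", period_ms=period,
                             classification_time_ms=t_c, seed=recording.seed,
                             config_hash=recording.config_hash)

    # anchored: arms/chirality from singularities near the scar rim
    n_arms, chirality = 1, 0
    if scar_spec is not None:
        f_now, f_prev = recording.frame_pair(t_c, tau)
        sings = detect_singularities(f_now, f_prev, t=t_c)
        rimd = _rim_distance_grid(frame.shape, scar_spec, recording.dx)
        near = [s for s in sings
                if rimd[int(s.row), int(s.col)] <= ANNULUS_CM]
        if near:
            charges = np.array([s.charge for s in near])
            chirality = int(np.sign(charges.sum())) or int(charges[0])
            n_arms = max(1, int((charges == chirality).sum()))
    label = ("anchored_multi" if n_arms >= 2 else
             "anchored_single_ccw" if chirality >= 0 else
             "anchored_single_cw")
    rec_out = OutcomeRecord(label=label, period_ms=period,
                            classification_time_ms=t_c, n_arms=n_arms,
                            chirality=chirality, seed=recording.seed,
                            config_hash=recording.config_hash)
    rec_out.time_to_event_s = time_to_anchor(recording, scar_spec,
                                             outcome=rec_out)
    return rec_out


def time_to_anchor(recording: SimRecording,
                   scar_spec: Optional[ScarSpec] = None,
                   outcome: Optional[OutcomeRecord] = None,
                   step_ms: float = 40.0,
                   period_threshold: float = PERIOD_THRESHOLD_MS,
                   window: float = PERIOD_WINDOW_MS) -> float:
    """Time (s) at which the final outcome establishes itself.

    For anchored runs: the earliest time from which the sliding-window period
    stays above the anchoring threshold until the end of the run (a transient
    excursion above threshold that later reverts is ignored).  For terminated
    runs: the time of the last suprathreshold node.  Undefined (ValueError)
    for not-anchored runs.
    """
    if outcome is None:
        outcome = classify(recording, scar_spec)
    if outcome.label == "not_anchored":
        raise ValueError("time to anchor is undefined for a not-anchored run")

    if outcome.label == "terminated":
        above = [float(t) for t, fr in zip(recording.frame_times, recording.frames)
                 if np.nanmax(fr) >= ACTIVATION_LEVEL_MV]
        return (above[-1] / 1000.0) if above else 0.0

    t_end = recording.probe_t[-1]
    t_first = recording.probe_t[0] + window
    ends = np.arange(t_end, t_first - 1e-9, -step_ms)[::-1]
    holds = np.array([measure_period(recording.probe_t, recording.probe_v,
                                     float(e), window) > period_threshold
                      for e in ends])
    # latest False, then everything after must hold
    bad = np.flatnonzero(~holds)
    if bad.size == 0:
        return float(max(0.0, (t_first - window)) / 1000.0)
    t_onset = ends[bad[-1]]  # threshold first holds after this window end
    return float(t_onset / 1000.0)


def singularity_track(recording: SimRecording,
                      times: Optional[Sequence[float]] = None,
                      tau: float = PHASE_TAU_MS) -> List[PhaseSingularity]:
    """All singularities detected on frame pairs at the requested times
    (default: every stored frame late enough to have a delayed partner)."""
    if times is None:
        times = [t for t in recording.frame_times
                 if t >= recording.frame_times[0] + tau]
    out: List[PhaseSingularity] = []
    for t in times:
        f_now, f_prev = recording.frame_pair(float(t), tau)
        out.extend(detect_singularities(f_now, f_prev, t=float(t)))
    return out


def mean_core_position(recording: SimRecording, t_start: float, t_end: float,
                       tau: float = PHASE_TAU_MS) -> Tuple[float, float]:
    """Time-averaged dominant-core position over [t_start, t_end] (grid
    coordinates).  At each stored frame pair the singularity closest to the
    running mean is taken, so short-lived shed pairs do not bias the
    average."""
    times = [t for t in recording.frame_times if t_start <= t <= t_end]
    if not times:
        raise ValueError("no stored frames in the requested window")
    mean_r = mean_c = None
    acc = []
    for t in times:
        f_now, f_prev = recording.frame_pair(float(t), tau)
        sings = detect_singularities(f_now, f_prev)
        if not sings:
            continue
        if mean_r is None:
            s = sings[0]
        else:
            s = min(sings, key=lambda x: np.hypot(x.row - mean_r,
                                                  x.col - mean_c))
        acc.append((s.row, s.col))
        mean_r = float(np.mean([a[0] for a in acc]))
        mean_c = float(np.mean([a[1] for a in acc]))
    if not acc:
        raise ValueError("no singularities found in the requested window")
    return (mean_r, mean_c)


def singularities_to_table(sings: Sequence[PhaseSingularity]):
    """Singularity track as a tidy DataFrame (t, row, col, charge) ready for
    ``DataFrame.to_csv``."""
    import pandas as pd

    return pd.DataFrame([{"t": s.t, "row": s.row, "col": s.col,
                          "charge": s.charge} for s in sings])


def tip_displacement(recording: SimRecording, t_ref: float, t_final: float,
                     tau: float = PHASE_TAU_MS) -> float:
    """Distance (cm) between the singularity position at ``t_ref`` and the
    one nearest to it at ``t_final`` (NaN if either frame shows none)."""
    ref = singularity_track(recording, [t_ref], tau)
    fin = singularity_track(recording, [t_final], tau)
    if not ref or not fin:
        return float("nan")
    r0 = ref[0]
    d = min(np.hypot(s.row - r0.row, s.col - r0.col) for s in fin)
    return float(d * recording.dx)
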