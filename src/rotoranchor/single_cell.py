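"""Single-cell TP06 integration utilities.

A single myocyte is the tissue kernel with one node and no neighbors; these
helpers wrap that case for pacing protocols, action-potential-duration
measurement and diastolic-threshold calibration.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from . import kernels, tp06
from .tp06 import CellParams, N_STATE

__all__ = ["integrate_cell", "paced_steady_state", "apd90",
           "diastolic_threshold"]

_NO_NBR = np.full((1, 4), -1, dtype=np.int32)


def integrate_cell(params: CellParams, duration: float, dt: float = 0.02,
                   y0: Optional[np.ndarray] = None,
                   stim_times: Sequence[float] = (),
                   stim_amplitude: float = 52.0, stim_duration: float = 1.0,
                   record_interval: float = 0.5,
                   dtype=np.float64) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one TP06 cell with forward Euler.

    Returns ``(t, V, y_end)`` with ``t``/``V`` sampled every
    ``record_interval`` ms and ``y_end`` the full final state (shape
    ``(N_STATE, 1)``).  ``stim_times`` lists onset times of depolarizing
    current pulses of ``stim_amplitude`` pA/pF lasting ``stim_duration`` ms.
    """
    tables = kernels.build_tables(params, dt, dtype=dtype)
    S = (tp06.resting_state(1, dtype=dtype) if y0 is None
         else np.ascontiguousarray(y0.reshape(N_STATE, 1).astype(dtype)))
    G = kernels.gates_from_state(S)
    jbuf = np.empty((4, 1), dtype=dtype)
    gna = np.array([params.g_na], dtype=dtype)
    gkr = np.array([params.g_kr * np.sqrt(params.ko / 5.4)], dtype=dtype)
    gks = np.array([params.g_ks], dtype=dtype)
    scratch = np.empty(1, dtype=dtype)
    ebufs = [np.empty(1, dtype=dtype) for _ in range(4)]
    stim = np.zeros(1, dtype=dtype)

    steps_per_chunk = max(1, int(round(record_interval / dt)))
    chunk = steps_per_chunk * dt
    n_chunks = int(round(duration / chunk))
    stim_windows = [(s, s + stim_duration) for s in stim_times]

    t_out = np.empty(n_chunks + 1)
    v_out = np.empty(n_chunks + 1)
    t_out[0], v_out[0] = 0.0, S[0, 0]
    for ci in range(1, n_chunks + 1):
        t0 = (ci - 1) * chunk
        amp = 0.0
        for a, b in stim_windows:
            if a < t0 + chunk and b > t0 + 1e-9:
                amp = stim_amplitude
        stim[0] = amp
        kernels.step_chunk(S, G, scratch, jbuf, _NO_NBR, gna, gkr, gks, stim,
                           *ebufs, tables.tb, tables.k1, tables.consts,
                           dt, 0.0, steps_per_chunk, 25)
        t_out[ci], v_out[ci] = ci * chunk, S[0, 0]
    kernels.sync_gates(S, G)
    if not np.isfinite(S).all():
        tp06._check_finite(S)
    return t_out, v_out, S


_PACED_CACHE: dict = {}


def paced_steady_state(params: CellParams, cl: float = 1000.0,
                       n_beats: int = 20, dt: float = 0.02,
                       dtype=np.float64) -> np.ndarray:
    """State after ``n_beats`` of pacing at cycle length ``cl`` ms, sampled
    at the end of the last diastolic interval (just before the next beat).
    Results are cached per parameter set (many tissue protocols start from
    this state)."""
    key = (tuple(sorted((k, v) for k, v in params.to_dict().items())),
           cl, n_beats, dt, np.dtype(dtype).str)
    if key not in _PACED_CACHE:
        stim_times = [i * cl for i in range(n_beats)]
        _, _, y = integrate_cell(params, duration=n_beats * cl, dt=dt,
                                 stim_times=stim_times, record_interval=1.0,
                                 dtype=dtype)
        _PACED_CACHE[key] = y
    return _PACED_CACHE[key].copy()


def apd90(t: np.ndarray, v: np.ndarray, stim_time: float = 0.0) -> float:
    """Action potential duration at 90 % repolarization from a V(t) trace.

    Measured from the maximal upstroke rate after ``stim_time`` to the
    downward crossing of ``V_rest + 0.1 * amplitude``, with linear
    interpolation at the crossing.
    """
    sel = t >= stim_time
    ts, vs = t[sel], v[sel]
    v_rest = vs[0]
    dv = np.diff(vs)
    up = int(np.argmax(dv))
    v_peak = float(vs.max())
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    below = np.flatnonzero(vs[up:] < v90)
    below = below[below > np.argmax(vs[up:])]
    if below.size == 0:
        return float("nan")
    k = up + below[0]
    # linear interpolation between samples k-1 and k
    t_cross = ts[k - 1] + (ts[k] - ts[k - 1]) * (vs[k - 1] - v90) / (vs[k - 1] - vs[k])
    return float(t_cross - ts[up])


_THRESHOLD_CACHE: dict = {}


def diastolic_threshold(params: CellParams, dt: float = 0.02,
                        cl: float = 1000.0, pulse_ms: float = 2.0) -> float:
    """Minimum 2-ms current amplitude (pA/pF) that elicits an action
    potential from the paced diastolic state, found by bisection and cached
    per parameter set."""
    key = (tuple(sorted((k, v) for k, v in params.to_dict().items())), dt, cl, pulse_ms)
    if key in _THRESHOLD_CACHE:
        return _THRESHOLD_CACHE[key]
    y0 = paced_steady_state(params, cl=cl, n_beats=5, dt=dt)

    def fires(amp: float) -> bool:
        _, v, _ = integrate_cell(params, duration=50.0, dt=dt, y0=y0,
                                 stim_times=[0.0], stim_amplitude=amp,
                                 stim_duration=pulse_ms)
        return v.max() > 0.0

    lo, hi = 0.0, 8.0
    while not fires(hi):
        hi *= 2.0
        if hi > 500.0:
            raise RuntimeError("no excitable response up to 500 pA/pF")
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    _THRESHOLD_CACHE[key] = hi
    return hi
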