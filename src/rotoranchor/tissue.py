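"""Discrete 2D ventricular tissue: grid, connectivity, integration, recording.

The tissue is a rectangular grid of nodes (250 um spacing by default).  Each
node is either a myocyte carrying a full TP06 state or an electrically
uncoupled, unexcitable obstacle ("fibroblast" in the diffuse-fibrosis sense).
Myocytes are coupled to their four von Neumann neighbors through identical
ohmic gap junctions of conductance ``g_gap``; edges to obstacles and across
the domain boundary carry no current, which realizes no-flux boundaries.

The membrane equation integrated here is

    C_m dV_i/dt = sum_j eta_ij g_gap (V_j - V_i) - I_ion,i

with eta the 0/1 connectivity tensor, advanced by forward Euler at a fixed
step (0.02 ms).  ``g_gap = 103.6 nS`` together with the default node
capacitance is calibrated so a planar wave at 1 Hz pacing travels at
72 cm/s (see docs/methods.md for the calibration).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import kernels, tp06
from .tp06 import CellParams, N_STATE

__all__ = [
    "DX_CM", "CM_PF",
    "TissueGrid", "ConnectivityTensor", "StimulusSpec", "SimConfig",
    "TissueState", "SimRecording", "build_connectivity", "coupling_current",
    "step", "run",
]

#: Node spacing in cm (250 x 250 um^2 per node).
DX_CM = 0.025

#: Node membrane capacitance (pF).  Fixed once by requiring a planar-wave
#: conduction velocity of 72 cm/s at CL 1000 ms with g_gap = 103.6 nS on the
#: default epicardial parameter set; see docs/methods.md.
CM_PF = 40.36


class SimulationError(RuntimeError):
    """Raised when the integration produces a non-finite voltage."""


@dataclass
class TissueGrid:
    """Rectangular tissue grid with obstacle mask and fibrosis field."""

    n_rows: int
    n_cols: int
    dx: float = DX_CM
    obstacle_mask: Optional[np.ndarray] = None
    fibrosis_map: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        shape = (self.n_rows, self.n_cols)
        if self.obstacle_mask is None:
            self.obstacle_mask = np.zeros(shape, dtype=bool)
        else:
            self.obstacle_mask = np.asarray(self.obstacle_mask, dtype=bool)
        if self.fibrosis_map is None:
            self.fibrosis_map = np.zeros(shape, dtype=float)
        else:
            self.fibrosis_map = np.asarray(self.fibrosis_map, dtype=float)
        if self.obstacle_mask.shape != shape or self.fibrosis_map.shape != shape:
            raise ValueError("mask/map shape does not match grid dimensions")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def myocyte_mask(self) -> np.ndarray:
        return ~self.obstacle_mask

    @property
    def n_myocytes(self) -> int:
        return int(self.myocyte_mask.sum())


@dataclass
class ConnectivityTensor:
    """Compressed von Neumann connectivity of the myocyte subgraph.

    ``active_index`` maps each myocyte to its flat grid index; ``neighbors``
    holds, for each myocyte, the compressed indices of its four neighbors in
    (up, down, left, right) order with -1 marking an uncoupled edge.
    Symmetry (i coupled to j iff j coupled to i) holds by construction.
    """

    shape: Tuple[int, int]
    active_index: np.ndarray   # (n,) int64 flat grid indices
    neighbors: np.ndarray      # (n, 4) int32

    @property
    def n_nodes(self) -> int:
        return self.active_index.shape[0]

    def coupling_counts(self) -> np.ndarray:
        """Number of conducting gap junctions per myocyte node."""
        return (self.neighbors >= 0).sum(axis=1)

    def positions(self) -> Tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the myocyte nodes."""
        return np.unravel_index(self.active_index, self.shape)


def build_connectivity(grid: TissueGrid) -> ConnectivityTensor:
    """Connectivity tensor coupling each myocyte to its myocyte von Neumann
    neighbors; obstacle and boundary edges are uncoupled (no-flux)."""
    rows, cols = grid.shape
    myo = grid.myocyte_mask
    flat_id = np.full(rows * cols, -1, dtype=np.int64)
    active = np.flatnonzero(myo.ravel())
    flat_id[active] = np.arange(active.size)
    grid_id = flat_id.reshape(rows, cols)

    nbr = np.full((active.size, 4), -1, dtype=np.int32)
    padded = np.full((rows + 2, cols + 2), -1, dtype=np.int64)
    padded[1:-1, 1:-1] = grid_id
    shifts = {0: (0, 1), 1: (2, 1), 2: (1, 0), 3: (1, 2)}  # up, down, left, right
    r_idx, c_idx = np.unravel_index(active, (rows, cols))
    for q, (dr, dc) in shifts.items():
        nbr[:, q] = padded[r_idx + dr, c_idx + dc]
    return ConnectivityTensor(shape=grid.shape, active_index=active, neighbors=nbr)


def coupling_current(conn: ConnectivityTensor, v_active: np.ndarray) -> np.ndarray:
    """Net dimensionless coupling term sum_j (V_j - V_i) per myocyte node.

    Multiplied by ``g_gap`` this is the total gap-junction current entering
    node i (pA); pairwise antisymmetry makes it sum to zero over the tissue.
    """
    v = np.asarray(v_active, dtype=float)
    nbr = conn.neighbors
    total = np.zeros_like(v)
    for q in range(4):
        has = nbr[:, q] >= 0
        total[has] += v[nbr[has, q]] - v[has]
    return total


@dataclass
class StimulusSpec:
    """External stimulus: a spatial mask driven with a constant current
    (pA/pF, positive = depolarizing) over a time window."""

    mask: np.ndarray
    start: float
    duration: float = 2.0
    amplitude: float = 52.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if not self.mask.any():
            raise ValueError("stimulus mask is empty")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class SimConfig:
    """Numerical and recording configuration of one tissue run."""

    duration: float
    dt: float = 0.02
    g_gap: float = 103.6          # nS
    cm_pf: float = CM_PF          # node capacitance, pF
    remodeling: bool = False
    precision: str = "double"     # "double" (default) | "single"
    frame_stride: Optional[float] = 10.0   # ms between stored V frames
    probe_interval: float = 1.0             # ms between probe samples
    probes: Optional[np.ndarray] = None     # (k, 2) row/col of probe nodes
    e_refresh: float = 0.5        # ms between reversal-potential refreshes
    seed: int = 0
    progress: bool = False

    def __post_init__(self):
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be > 0 and duration >= 0")
        if self.g_gap < 0:
            raise ValueError("g_gap must be >= 0")
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")
        if self.probe_interval > 1.0:
            raise ValueError("probe sampling interval must be <= 1 ms")
        if self.probes is not None:
            self.probes = np.atleast_2d(np.asarray(self.probes, dtype=int))

    @property
    def dtype(self):
        return np.float32 if self.precision == "single" else np.float64

    def hash(self, params: CellParams) -> str:
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("probes", "progress")}
        payload["probes"] = None if self.probes is None else self.probes.tolist()
        payload["params"] = params.to_dict()
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=float)
                            .encode()).hexdigest()[:12]


@dataclass
class TissueState:
    """Compressed per-myocyte TP06 state at one instant."""

    S: np.ndarray              # (N_STATE, n)
    conn: ConnectivityTensor
    t: float = 0.0

    def voltage_frame(self, fill=np.nan) -> np.ndarray:
        frame = np.full(self.conn.shape, fill, dtype=float)
        frame.ravel()[self.conn.active_index] = self.S[0]
        return frame

    def copy(self) -> "TissueState":
        return TissueState(S=self.S.copy(), conn=self.conn, t=self.t)


@dataclass
class SimRecording:
    """Time-indexed output of one run: strided V frames plus probe traces."""

    frame_times: np.ndarray        # (T,)
    frames: np.ndarray             # (T, n_rows, n_cols) float32, NaN = obstacle
    probe_t: np.ndarray            # (Tp,)
    probe_v: np.ndarray            # (k, Tp)
    probe_rc: np.ndarray           # (k, 2)
    config_hash: str = ""
    seed: int = 0
    dt: float = 0.02
    dx: float = DX_CM
    final_state: Optional[TissueState] = None
    meta: dict = field(default_factory=dict)

    def frame_at(self, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.frame_times - t)))
        return self.frames[k]

    def frame_pair(self, t: float, tau: float) -> Tuple[np.ndarray, np.ndarray]:
        """Frames nearest t and t - tau (for phase construction)."""
        return self.frame_at(t), self.frame_at(t - tau)

    @property
    def duration(self) -> float:
        return float(self.probe_t[-1]) if self.probe_t.size else 0.0

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("frames/t", data=self.frame_times)
            fh.create_dataset("frames/V", data=self.frames, compression="gzip", compression_opts=1)
            fh.create_dataset("probes/t", data=self.probe_t)
            fh.create_dataset("probes/V", data=self.probe_v)
            fh.create_dataset("probes/rc", data=self.probe_rc)
            fh.attrs["config_hash"] = self.config_hash
            fh.attrs["seed"] = self.seed
            fh.attrs["dt"] = self.dt
            fh.attrs["dx"] = self.dx
            fh.attrs["meta"] = json.dumps(self.meta, default=float)

    @classmethod
    def load(cls, path) -> "SimRecording":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                frame_times=fh["frames/t"][...],
                frames=fh["frames/V"][...],
                probe_t=fh["probes/t"][...],
                probe_v=fh["probes/V"][...],
                probe_rc=fh["probes/rc"][...],
                config_hash=str(fh.attrs["config_hash"]),
                seed=int(fh.attrs["seed"]),
                dt=float(fh.attrs["dt"]),
                dx=float(fh.attrs["dx"]),
                meta=json.loads(fh.attrs["meta"]),
            )


def _initial_state(grid: TissueGrid, conn: ConnectivityTensor, config: SimConfig,
                   initial) -> TissueState:
    n = conn.n_nodes
    dtype = config.dtype
    if isinstance(initial, TissueState):
        if initial.S.shape != (N_STATE, n):
            raise ValueError("initial state does not match grid myocyte count")
        return TissueState(S=initial.S.astype(dtype), conn=conn, t=0.0)
    if isinstance(initial, np.ndarray):
        if initial.shape == (N_STATE,):
            S = np.repeat(initial[:, None], n, axis=1).astype(dtype)
            return TissueState(S=S, conn=conn, t=0.0)
        if initial.shape == (N_STATE, n):
            return TissueState(S=initial.astype(dtype), conn=conn, t=0.0)
        raise ValueError("initial array must be (N_STATE,) or (N_STATE, n_myocytes)")
    if initial == "rest":
        return TissueState(S=tp06.resting_state(n, dtype=dtype), conn=conn, t=0.0)
    raise ValueError(f"unrecognized initial condition {initial!r}")


def _node_conductances(grid: TissueGrid, conn: ConnectivityTensor,
                       params: CellParams, remodeling: bool, dtype):
    n = conn.n_nodes
    gna = np.full(n, params.g_na, dtype=np.float64)
    gkr = np.full(n, params.g_kr * np.sqrt(params.ko / 5.4), dtype=np.float64)
    gks = np.full(n, params.g_ks, dtype=np.float64)
    if remodeling:
        f_local = grid.fibrosis_map.ravel()[conn.active_index]
        s_na, s_kr, s_ks = tp06.remodeling_factors(np.clip(f_local, 0.0, 100.0))
        gna *= s_na
        gkr *= s_kr
        gks *= s_ks
    return gna.astype(dtype), gkr.astype(dtype), gks.astype(dtype)


def step(state: TissueState, grid: TissueGrid, conn: ConnectivityTensor,
         config: SimConfig, params: Optional[CellParams] = None,
         stim: Optional[np.ndarray] = None, n_steps: int = 1) -> TissueState:
    """Advance ``state`` by ``n_steps`` forward-Euler steps and return it.

    Obstacle nodes are not represented and therefore untouched.  This is the
    one-step surface used by the tests; long runs should use :func:`run`,
    which amortizes table construction and records output.
    """
    params = params or CellParams.calibrated()
    dtype = config.dtype
    tables = kernels.build_tables(params, config.dt, dtype=dtype)
    gna, gkr, gks = _node_conductances(grid, conn, params, config.remodeling, dtype)
    n = conn.n_nodes
    stim_arr = np.zeros(n, dtype=dtype) if stim is None else stim.astype(dtype)
    S = np.ascontiguousarray(state.S.astype(dtype))
    G = kernels.gates_from_state(S)
    jbuf = np.empty((4, n), dtype=dtype)
    scratch = np.empty(n, dtype=dtype)
    e_bufs = [np.empty(n, dtype=dtype) for _ in range(4)]
    kernels.step_chunk(S, G, scratch, jbuf, conn.neighbors, gna, gkr, gks,
                       stim_arr, *e_bufs, tables.tb, tables.k1, tables.consts,
                       config.dt, config.g_gap / config.cm_pf, n_steps, 1)
    kernels.sync_gates(S, G)
    out = TissueState(S=S, conn=conn, t=state.t + n_steps * config.dt)
    if not np.all(np.isfinite(S[0])):
        bad = conn.active_index[int(np.flatnonzero(~np.isfinite(S[0]))[0])]
        r, c = np.unravel_index(bad, conn.shape)
        raise SimulationError(f"non-finite voltage at node ({r}, {c}), t = {out.t:.2f} ms")
    return out


def run(grid: TissueGrid, config: SimConfig,
        stimuli: Sequence[StimulusSpec] = (),
        initial: Union[str, np.ndarray, TissueState] = "rest",
        params: Optional[CellParams] = None,
        stop_when: Optional[Callable[[float, np.ndarray], bool]] = None,
        conn: Optional[ConnectivityTensor] = None,
        t0: float = 0.0) -> SimRecording:
    """Integrate the tissue for ``config.duration`` ms and record output.

    Deterministic given (grid, config, stimuli, initial): the integrator
    itself draws no random numbers; ``config.seed`` is only stamped into the
    recording so textures and runs can be traced back.

    Parameters
    ----------
    stop_when : optional callable ``(t_ms, V_active) -> bool``
        Checked at every probe interval; returning True ends the run early
        (used e.g. for conduction-block detection).  The recording's metadata
        notes the actual end time.
    t0 : recording-time offset (ms) so multi-phase protocols can stitch
        consecutive runs onto one time axis; stimulus times stay relative to
        the start of this run.

    Raises
    ------
    SimulationError
        If any nodal voltage becomes non-finite (with location and time).
    """
    params = params or CellParams.calibrated()
    params.validate()
    if conn is None:
        conn = build_connectivity(grid)
    n = conn.n_nodes
    dtype = config.dtype
    state = _initial_state(grid, conn, config, initial)
    S = np.ascontiguousarray(state.S)
    tables = kernels.build_tables(params, config.dt, dtype=dtype)
    gna, gkr, gks = _node_conductances(grid, conn, params, config.remodeling, dtype)
    k_coup = config.g_gap / config.cm_pf
    G = kernels.gates_from_state(S)
    jbuf = np.empty((4, n), dtype=dtype)
    scratch = np.empty(n, dtype=dtype)
    e_bufs = [np.empty(n, dtype=dtype) for _ in range(4)]

    # compressed stimulus masks
    stim_masks = [s.mask.ravel()[conn.active_index] for s in stimuli]

    chunk_ms = config.probe_interval
    steps_per_chunk = max(1, int(round(chunk_ms / config.dt)))
    chunk_ms = steps_per_chunk * config.dt
    n_chunks = int(round(config.duration / chunk_ms))
    e_stride = max(1, int(round(config.e_refresh / config.dt)))

    if config.probes is None:
        probe_rc = np.zeros((0, 2), dtype=int)
    else:
        probe_rc = config.probes
    probe_ids = np.array(
        [_probe_to_active(conn, r, c) for r, c in probe_rc], dtype=np.int64
    )

    frame_every = (None if config.frame_stride is None
                   else max(1, int(round(config.frame_stride / chunk_ms))))

    probe_t = [t0]
    probe_v = [S[0][probe_ids].astype(np.float32)]
    frame_times = [t0]
    frames = [_to_frame(S[0], conn)]

    iterator = range(1, n_chunks + 1)
    if config.progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="simulate", unit="ms")

    stim_arr = np.zeros(n, dtype=dtype)
    stopped_at = None
    for ci in iterator:
        t_chunk = (ci - 1) * chunk_ms   # run-local time; stimuli are relative
        stim_arr[:] = 0.0
        for spec, cmask in zip(stimuli, stim_masks):
            # stimulus active during any overlap with this chunk
            if spec.start < t_chunk + chunk_ms and spec.end > t_chunk + 1e-9:
                stim_arr[cmask] += spec.amplitude
        kernels.step_chunk(S, G, scratch, jbuf, conn.neighbors, gna, gkr, gks,
                           stim_arr, *e_bufs, tables.tb, tables.k1, tables.consts,
                           config.dt, k_coup, steps_per_chunk, e_stride)
        t = t0 + ci * chunk_ms
        probe_t.append(t)
        probe_v.append(S[0][probe_ids].astype(np.float32))
        if frame_every is not None and ci % frame_every == 0:
            frame_times.append(t)
            frames.append(_to_frame(S[0], conn))
        if ci % 10 == 0 and not np.isfinite(S[0]).all():
            bad = conn.active_index[int(np.flatnonzero(~np.isfinite(S[0]))[0])]
            r, c = np.unravel_index(bad, conn.shape)
            raise SimulationError(f"non-finite voltage at node ({r}, {c}), t = {t:.2f} ms")
        if stop_when is not None and stop_when(t, S[0]):
            stopped_at = t
            break

    kernels.sync_gates(S, G)
    if not np.isfinite(S).all():
        raise SimulationError("non-finite state at end of run")

    final_t = probe_t[-1]
    if frame_every is None or frame_times[-1] != final_t:
        frame_times.append(final_t)
        frames.append(_to_frame(S[0], conn))

    rec = SimRecording(
        frame_times=np.asarray(frame_times),
        frames=np.stack(frames),
        probe_t=np.asarray(probe_t),
        probe_v=np.stack(probe_v, axis=1) if probe_ids.size else np.zeros((0, len(probe_t))),
        probe_rc=probe_rc,
        config_hash=config.hash(params),
        seed=config.seed,
        dt=config.dt,
        dx=grid.dx,
        final_state=TissueState(S=S, conn=conn, t=final_t),
        meta={"stopped_at": stopped_at, "duration": config.duration,
              "remodeling": config.remodeling, "precision": config.precision},
    )
    return rec


def _probe_to_active(conn: ConnectivityTensor, r: int, c: int) -> int:
    flat = r * conn.shape[1] + c
    pos = np.searchsorted(conn.active_index, flat)
    if pos >= conn.active_index.size or conn.active_index[pos] != flat:
        raise ValueError(f"probe ({r}, {c}) lies on an obstacle node")
    return int(pos)


def _to_frame(v_active: np.ndarray, conn: ConnectivityTensor) -> np.ndarray:
    frame = np.full(conn.shape[0] * conn.shape[1], np.nan, dtype=np.float32)
    frame[conn.active_index] = v_active
    return frame.reshape(conn.shape)


def concat_recordings(parts: Sequence[SimRecording]) -> SimRecording:
    """Stitch consecutive recordings (produced with increasing ``t0``) into
    one; duplicate boundary samples are dropped."""
    if not parts:
        raise ValueError("no recordings to concatenate")
    frame_t, frames, probe_t, probe_v = [], [], [], []
    for k, rec in enumerate(parts):
        ft, fv, pt, pv = rec.frame_times, rec.frames, rec.probe_t, rec.probe_v
        if k > 0:
            keep_f = ft > frame_t[-1][-1] + 1e-9
            keep_p = pt > probe_t[-1][-1] + 1e-9
            ft, fv, pt, pv = ft[keep_f], fv[keep_f], pt[keep_p], pv[:, keep_p]
        frame_t.append(ft)
        frames.append(fv)
        probe_t.append(pt)
        probe_v.append(pv)
    last = parts[-1]
    return SimRecording(
        frame_times=np.concatenate(frame_t),
        frames=np.concatenate(frames),
        probe_t=np.concatenate(probe_t),
        probe_v=np.concatenate(probe_v, axis=1),
        probe_rc=last.probe_rc,
        config_hash=last.config_hash, seed=last.seed, dt=last.dt, dx=last.dx,
        final_state=last.final_state,
        meta={"concatenated": len(parts), **last.meta},
    )


def crop_state(state: TissueState, row0: int, col0: int,
               new_grid: TissueGrid) -> TissueState:
    """Transplant a tissue state into a sub-window (optionally with new
    obstacles).

    Node (r, c) of ``new_grid`` receives the state of node
    (r + row0, c + col0) of the source; nodes that are obstacles in the new
    grid are dropped.  Spiral arms cut by the new boundary end on the no-flux
    edge, which is the standard way to continue an established rotor in a
    smaller domain.
    """
    old_conn = state.conn
    rows_new, cols_new = new_grid.shape
    old_rows, old_cols = old_conn.shape
    if row0 < 0 or col0 < 0 or row0 + rows_new > old_rows \
            or col0 + cols_new > old_cols:
        raise ValueError("crop window exceeds the source domain")
    # flat old index for every new myocyte node
    new_conn = build_connectivity(new_grid)
    r2, c2 = np.unravel_index(new_conn.active_index, new_grid.shape)
    old_flat = (r2 + row0) * old_cols + (c2 + col0)
    pos = np.searchsorted(old_conn.active_index, old_flat)
    if np.any(pos >= old_conn.active_index.size) or \
            np.any(old_conn.active_index[pos] != old_flat):
        raise ValueError("crop window covers obstacle nodes of the source")
    return TissueState(S=np.ascontiguousarray(state.S[:, pos]),
                       conn=new_conn, t=state.t)
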