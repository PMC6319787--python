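"""Experiment drivers: rotor-vs-scar simulations at configurable scale.

Each driver reproduces one of the study's computational experiments as a
tidy table of per-run outcome records:

* ``run_showcase`` — one rotor initiated at a given distance from a
  radial-gradient scar (the dynamical-anchoring sequence).
* ``run_distance_sweep`` — outcome type vs initial rotor-to-scar distance.
* ``run_anchor_time`` — time to anchoring/termination vs distance, with and
  without ionic remodeling, plus linear fits per arm.
* ``run_phase_diagram`` — anchored fraction over (scar diameter, uniform
  fibrosis level), labelled "Attraction" above a 65 % anchored fraction.
* ``run_controls`` — no-scar and necrotic-only control runs (stable rotor,
  no anchoring).

The full-scale study (25.6 x 12.8 cm sheet, 40 s per run, 60-300 textures
per grid point) needs a cluster; the desk defaults here (12.8 x 6.4 cm,
20 s, 10 textures) keep single runs in the minutes range while preserving
the mechanism.  Every row records its seed, configuration hash and scale so
any single run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import analysis, protocols, scar, tissue
from .analysis import OutcomeRecord
from .protocols import S1S2Spec, ProtocolFailure, initiate_rotor
from .scar import ScarSpec
from .tissue import DX_CM, SimConfig, StimulusSpec, TissueGrid, run
from .tp06 import CellParams

__all__ = ["SweepSpec", "scar_ring_probes", "run_showcase",
           "run_distance_sweep", "run_anchor_time", "run_phase_diagram",
           "run_controls", "fit_anchor_times", "attraction_label"]

ATTRACTION_FRACTION = 0.65


@dataclass
class SweepSpec:
    """Scale and sampling of one experiment sweep."""

    domain: Tuple[int, int] = (256, 512)      # (rows, cols); 6.4 x 12.8 cm
    duration_s: float = 20.0
    textures_per_point: int = 10
    distances_cm: Sequence[float] = (2.0, 3.0, 4.0, 5.0)
    diameters_cm: Sequence[float] = (1.6, 2.6, 3.6, 4.6)
    levels_pct: Sequence[float] = (10.0, 20.0, 30.0, 40.0)
    scar_diameter_cm: float = 6.4
    scar_level_pct: float = 50.0
    phase_distance_cm: float = 5.0
    remodeling: bool = False
    base_seed: int = 0
    paper_scale: bool = False
    progress: bool = False

    def __post_init__(self):
        if self.textures_per_point < 1:
            raise ValueError("textures_per_point must be >= 1")
        if self.paper_scale:
            self.domain = (512, 1024)
            self.duration_s = 40.0

    @property
    def classification_time_ms(self) -> float:
        return self.duration_s * 1000.0

    def meta(self) -> dict:
        return {"domain": self.domain, "duration_s": self.duration_s,
                "paper_scale": self.paper_scale,
                "remodeling": self.remodeling}


def _scar_center(spec: SweepSpec, diameter_cm: float) -> Tuple[int, int]:
    rows, cols = spec.domain
    rad_nodes = int(round(diameter_cm / 2.0 / DX_CM))
    margin = 8
    return (rows // 2, cols - margin - rad_nodes - 1)


def scar_ring_probes(grid: TissueGrid, sspec: ScarSpec, n_ring: int = 16,
                     ring_offset_cm: float = 1.0) -> np.ndarray:
    """Probe layout for outcome classification: ``n_ring`` probes on a circle
    ``ring_offset_cm`` outside the scar rim (snapped to the nearest myocyte)
    plus 4 far-field probes, so both an anchored rotor's period and a distant
    free rotor are observable."""
    rows, cols = grid.shape
    r0, c0 = sspec.center
    rad = (sspec.radius_cm + ring_offset_cm) / grid.dx
    myo = grid.myocyte_mask
    probes = []
    for ang in np.linspace(0, 2 * np.pi, n_ring, endpoint=False):
        rr = int(round(r0 + rad * np.sin(ang)))
        cc = int(round(c0 + rad * np.cos(ang)))
        rr = min(max(rr, 0), rows - 1)
        cc = min(max(cc, 0), cols - 1)
        if not myo[rr, cc]:
            # walk outward along the radius until off the obstacle
            for extra in range(1, 40):
                r2 = int(round(r0 + (rad + extra) * np.sin(ang)))
                c2 = int(round(c0 + (rad + extra) * np.cos(ang)))
                if 0 <= r2 < rows and 0 <= c2 < cols and myo[r2, c2]:
                    rr, cc = r2, c2
                    break
            else:
                continue
        probes.append((rr, cc))
    for rr, cc in [(rows // 4, cols // 8), (3 * rows // 4, cols // 8),
                   (rows // 4, cols // 4), (3 * rows // 4, cols // 4)]:
        if myo[rr, cc]:
            probes.append((rr, cc))
    return np.array(sorted(set(probes)))


def _one_run(grid: TissueGrid, sspec: Optional[ScarSpec], spec: SweepSpec,
             distance_cm: float, seed: int,
             params: Optional[CellParams] = None,
             frame_stride: float = 10.0) -> Tuple[OutcomeRecord, tissue.SimRecording]:
    """Initiate a rotor ``distance_cm`` left of the scar rim and classify the
    full run at the configured classification time."""
    params = params or CellParams.calibrated()
    rows, cols = grid.shape
    if sspec is not None:
        rim_col = sspec.center[1] - int(round(sspec.radius_cm / DX_CM))
        tip_col = rim_col - int(round(distance_cm / DX_CM))
        probes = scar_ring_probes(grid, sspec)
    else:
        tip_col = cols // 2
        probes = np.array([(rows // 4, cols // 4), (rows // 4, 3 * cols // 4),
                           (3 * rows // 4, cols // 4),
                           (3 * rows // 4, 3 * cols // 4),
                           (rows // 2, cols // 2 + rows // 4)])
    tip = (rows // 2, tip_col)
    if tip_col < 12:
        raise ValueError(f"distance {distance_cm} cm does not fit in the domain")

    base = SimConfig(duration=0.0, remodeling=spec.remodeling, seed=seed,
                     progress=spec.progress)
    rec_init, state = initiate_rotor(grid, S1S2Spec(tip_rc=tip), params=params,
                                     config=base, probes=probes)
    t_done = float(rec_init.probe_t[-1])
    cfg = SimConfig(duration=spec.classification_time_ms - t_done,
                    remodeling=spec.remodeling, frame_stride=frame_stride,
                    probes=probes, seed=seed, progress=spec.progress)
    rec_main = run(grid, cfg, [], initial=state, params=params, t0=t_done)
    full = tissue.concat_recordings([rec_init, rec_main])
    outcome = analysis.classify(full, sspec,
                                classification_time=spec.classification_time_ms)
    outcome.extra.update({"distance_cm": distance_cm, **spec.meta()})
    return outcome, full


def run_showcase(spec: Optional[SweepSpec] = None, distance_cm: float = 4.0,
                 seed: int = 0, keep_recording: bool = True):
    """One gradient-scar run (the anchoring sequence): returns
    ``(OutcomeRecord, SimRecording)``."""
    spec = spec or SweepSpec()
    sspec = ScarSpec(center=_scar_center(spec, spec.scar_diameter_cm),
                     diameter=spec.scar_diameter_cm, profile="radial_linear",
                     level=spec.scar_level_pct)
    grid = scar.make_scar_grid(sspec, spec.domain, seed)
    outcome, rec = _one_run(grid, sspec, spec, distance_cm, seed)
    return (outcome, rec) if keep_recording else (outcome, None)


def _sweep_rows(spec, point_iter) -> pd.DataFrame:
    rows = []
    sort_keys: List[str] = []
    for p_i, (build, meta) in enumerate(point_iter):
        sort_keys = sort_keys or list(meta.keys())
        for k in range(spec.textures_per_point):
            # disjoint seed blocks per sweep point; failures are recorded,
            # never dropped
            seed = spec.base_seed + 10_000 * p_i + k
            try:
                outcome = build(seed)
                row = outcome.row()
            except (ProtocolFailure, tissue.SimulationError,
                    ValueError) as exc:
                row = {"label": "failed", "error": str(exc), "seed": seed}
            row.update(meta)
            rows.append(row)
    return (pd.DataFrame(rows).sort_values(sort_keys + ["seed"])
            .reset_index(drop=True))


def run_distance_sweep(spec: Optional[SweepSpec] = None) -> pd.DataFrame:
    """Outcome label per (initial distance, texture seed) for the gradient
    scar, plus per-distance outcome fractions (recomputable from the rows)."""
    spec = spec or SweepSpec()
    sspec = ScarSpec(center=_scar_center(spec, spec.scar_diameter_cm),
                     diameter=spec.scar_diameter_cm, profile="radial_linear",
                     level=spec.scar_level_pct)

    def point(distance):
        def build(seed):
            grid = scar.make_scar_grid(sspec, spec.domain, seed)
            outcome, _ = _one_run(grid, sspec, spec, distance, seed)
            return outcome
        return build, {"distance_cm": distance}

    return _sweep_rows(spec, (point(d) for d in spec.distances_cm))


def run_anchor_time(spec: Optional[SweepSpec] = None) -> pd.DataFrame:
    """Time to anchoring/termination vs distance, one arm with and one
    without ionic remodeling."""
    spec = spec or SweepSpec()
    sspec = ScarSpec(center=_scar_center(spec, spec.scar_diameter_cm),
                     diameter=spec.scar_diameter_cm, profile="radial_linear",
                     level=spec.scar_level_pct)

    def point(distance, remodeling):
        arm_spec = replace(spec, remodeling=remodeling)

        def build(seed):
            grid = scar.make_scar_grid(sspec, spec.domain, seed)
            outcome, _ = _one_run(grid, sspec, arm_spec, distance, seed)
            return outcome
        return build, {"distance_cm": distance, "remodeling": remodeling}

    pts = [point(d, rem) for rem in (False, True) for d in spec.distances_cm]
    return _sweep_rows(spec, iter(pts))


def fit_anchor_times(df: pd.DataFrame) -> Dict[bool, dict]:
    """Least-squares line (time_to_event_s vs distance_cm) per remodeling
    arm, with 95 % CIs on slope and intercept."""
    out = {}
    for rem, sub in df[df["label"] != "failed"].groupby("remodeling"):
        sub = sub.dropna(subset=["time_to_event_s"])
        res = stats.linregress(sub["distance_cm"], sub["time_to_event_s"])
        n = len(sub)
        tcrit = stats.t.ppf(0.975, max(n - 2, 1))
        out[bool(rem)] = {
            "slope_s_per_cm": res.slope,
            "slope_ci": (res.slope - tcrit * res.stderr,
                         res.slope + tcrit * res.stderr),
            "intercept_s": res.intercept,
            "intercept_ci": (res.intercept - tcrit * res.intercept_stderr,
                             res.intercept + tcrit * res.intercept_stderr),
            "r": res.rvalue, "n": n,
        }
    return out


def attraction_label(frac_anchored: float) -> str:
    return "Attraction" if frac_anchored > ATTRACTION_FRACTION else "No Attraction"


def run_phase_diagram(spec: Optional[SweepSpec] = None) -> pd.DataFrame:
    """Anchored fraction over (uniform-fibrosis level, scar diameter) with
    the rotor initiated a fixed distance from the rim."""
    spec = spec or SweepSpec()

    def point(diameter, level):
        sspec = ScarSpec(center=_scar_center(spec, diameter),
                         diameter=diameter, profile="uniform", level=level)

        def build(seed):
            grid = scar.make_scar_grid(sspec, spec.domain, seed)
            outcome, _ = _one_run(grid, sspec, spec,
                                  spec.phase_distance_cm, seed)
            return outcome
        return build, {"diameter_cm": diameter, "level_pct": level}

    pts = [point(dia, lev) for dia in spec.diameters_cm
           for lev in spec.levels_pct]
    df = _sweep_rows(spec, iter(pts))
    agg = (df[df["label"] != "failed"]
           .assign(anchored=lambda x: x["label"].str.startswith("anchored"))
           .groupby(["diameter_cm", "level_pct"])["anchored"].mean()
           .rename("fraction_anchored").reset_index())
    agg["region"] = agg["fraction_anchored"].map(attraction_label)
    return df.merge(agg, on=["diameter_cm", "level_pct"], how="left")


def run_controls(spec: Optional[SweepSpec] = None, distance_cm: float = 4.0,
                 seed: int = 0) -> pd.DataFrame:
    """No-scar and necrotic-only control runs: the rotor stays where it was
    initiated and is never classified as anchored."""
    spec = spec or SweepSpec()
    sspec = ScarSpec(center=_scar_center(spec, spec.scar_diameter_cm),
                     diameter=spec.scar_diameter_cm, level=spec.scar_level_pct)
    no_scar, necrotic = scar.make_controls(sspec, spec.domain)
    rows = []
    for name, grid, use_spec in (("no_scar", no_scar, None),
                                 ("necrotic_only", necrotic, sspec)):
        outcome, rec = _one_run(grid, use_spec, spec, distance_cm, seed)
        t0 = rec.frame_times[0] + analysis.PHASE_TAU_MS + 100.0
        disp = analysis.tip_displacement(rec, t_ref=float(t0),
                                         t_final=float(rec.frame_times[-1]))
        row = outcome.row()
        row.update({"control": name, "tip_displacement_cm": disp})
        rows.append(row)
    return pd.DataFrame(rows)
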