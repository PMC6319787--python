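"""ten Tusscher–Panfilov 2006 (TP06) human ventricular myocyte model.

This module defines the ionic model used by every simulation in the package:
parameter sets (:class:`CellParams`), the resting state, vectorized evaluation
of gate kinetics and membrane currents, a forward-Euler single-step update
(:func:`step_cell`), and the fibrosis-dependent ionic-remodeling scaling
(:func:`remodeling_factors`, :func:`apply_remodeling`).

Units follow the TP06 convention throughout: voltage in mV, time in ms,
concentrations in mM, currents in pA/pF (i.e. normalized per membrane
capacitance).  Calcium buffering in cytosol, subspace and SR is treated as
instantaneous (rapid-buffering projection), exactly as in the published model.

The functions here are plain NumPy and operate on state arrays of shape
``(N_STATE, n)`` so the same code serves a single cell (``n = 1``) and acts as
the reference path for the JIT-compiled tissue kernel in
:mod:`rotoranchor.kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "CellParams",
    "RemodelingFactors",
    "STATE_NAMES",
    "N_STATE",
    "resting_state",
    "gate_tables",
    "compute_currents",
    "ionic_total_current",
    "step_cell",
    "remodeling_factors",
    "apply_remodeling",
]

# Physical constants (TP06 values)
R_GAS = 8314.472     # J / (kmol K)
FARADAY = 96485.3415  # C / mol
TEMP = 310.0          # K
RTONF = R_GAS * TEMP / FARADAY  # ~26.714 mV

# Delayed-rectifier scale factors of the calibrated tissue parameter set
# (fixed once against the 72 cm/s planar CV and ~222 ms rotor-period
# calibration surface; see CellParams.calibrated and docs/methods.md).
IKR_CALIBRATION_SCALE = 1.12
IKS_CALIBRATION_SCALE = 1.12

# State vector layout.  V first, then gates, then Ca-release gate and
# concentrations.  Order is load-bearing: the tissue kernel indexes by it.
STATE_NAMES = (
    "V", "m", "h", "j", "xr1", "xr2", "xs", "r", "s",
    "d", "f", "f2", "fcass", "rr", "cai", "casr", "cass", "nai", "ki",
)
N_STATE = len(STATE_NAMES)

_GATES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2")
IDX = {name: k for k, name in enumerate(STATE_NAMES)}


@dataclass
class CellParams:
    """TP06 parameter set.

    ``variant`` names the transmural cell type ("epi", "endo", "M"); the
    conductances below are peak values in nS/pF (or, for ``g_cal``, the TP06
    permeability in cm^3/(uF s) units) as in the original publication.
    """

    variant: str = "epi"
    # Peak conductances / permeabilities
    g_na: float = 14.838
    g_k1: float = 5.405
    g_kr: float = 0.153
    g_ks: float = 0.392
    g_to: float = 0.294
    g_cal: float = 3.980e-5
    g_bna: float = 0.00029
    g_bca: float = 0.000592
    g_pca: float = 0.1238
    g_pk: float = 0.0146
    k_nak: float = 2.724
    k_naca: float = 1000.0
    # External concentrations (mM)
    ko: float = 5.4
    nao: float = 140.0
    cao: float = 2.0
    # Exchanger / pump constants
    km_k: float = 1.0
    km_na: float = 40.0
    km_nai: float = 87.5
    km_ca: float = 1.38
    k_sat: float = 0.1
    gamma: float = 0.35
    alpha_naca: float = 2.5
    kp_ca: float = 0.0005
    p_kna: float = 0.03
    # SR calcium handling
    v_maxup: float = 0.006375
    k_up: float = 0.00025
    v_rel: float = 0.102
    k1_rel: float = 0.15
    k2_rel: float = 0.045
    k3_rel: float = 0.060
    k4_rel: float = 0.005
    ec_sr: float = 1.5
    max_sr: float = 2.5
    min_sr: float = 1.0
    v_leak: float = 0.00036
    v_xfer: float = 0.0038
    # Buffering
    buf_c: float = 0.2
    k_buf_c: float = 0.001
    buf_sr: float = 10.0
    k_buf_sr: float = 0.3
    buf_ss: float = 0.4
    k_buf_ss: float = 0.00025
    # Cell geometry (TP06 volume units) and capacitance factor
    v_c: float = 0.016404
    v_sr: float = 0.001094
    v_ss: float = 0.00005468
    capacitance: float = 0.185
    # Gate-kinetics scale factors (restitution tuning; 1.0 = published TP06)
    tau_f_scale: float = 1.0
    tau_f2_scale: float = 1.0

    @classmethod
    def epicardial(cls) -> "CellParams":
        return cls(variant="epi")

    @classmethod
    def calibrated(cls) -> "CellParams":
        """The package's tissue parameter set: epicardial TP06 with I_Kr and
        I_Ks scaled up so that, together with the gap-junction coupling
        (g_gap = 103.6 nS, C_m = 40.36 pF), planar CV at CL 1000 ms is
        72 cm/s and a free rotor turns at ~222 ms.  The published epicardial
        set yields a slower (~237 ms), meandering rotor; the faster
        delayed-rectifier repolarization shortens APD at high rate and
        stabilizes the core, reproducing the stationary ~222 ms rotor the
        tissue experiments assume.  See docs/methods.md (calibration)."""
        base = cls(variant="epi")
        return replace(base, g_kr=base.g_kr * IKR_CALIBRATION_SCALE,
                       g_ks=base.g_ks * IKS_CALIBRATION_SCALE)

    @classmethod
    def endocardial(cls) -> "CellParams":
        return cls(variant="endo", g_ks=0.392, g_to=0.073)

    @classmethod
    def midmyocardial(cls) -> "CellParams":
        return cls(variant="M", g_ks=0.098, g_to=0.294)

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "CellParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        """Serialize the parameter set as a plain-text YAML file."""
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CellParams":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        for name, val in self.to_dict().items():
            if name == "variant":
                continue
            if not np.isfinite(val):
                raise ValueError(f"parameter {name!r} is not finite")
            if name.startswith(("g_", "k_", "km_", "v_", "buf_")) and val < 0:
                raise ValueError(f"conductance/rate {name!r} must be >= 0, got {val}")


@dataclass(frozen=True)
class RemodelingFactors:
    """Multiplicative conductance scale factors for fibrotic remodeling."""

    s_na: float
    s_kr: float
    s_ks: float

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.s_na, self.s_kr, self.s_ks)


def remodeling_factors(f):
    """Conductance scale factors for I_Na, I_Kr, I_Ks at local fibrosis ``f``.

    The fibrotic down-regulation is linear in the local fibrosis percentage:
    ``G_Na = (1 - 1.55 f/100) G_Na0``, ``G_Kr = (1 - 1.75 f/100) G_Kr0``,
    ``G_Ks = (1 - 2 f/100) G_Ks0``, clamped at zero where the linear formula
    would go negative (a conductance cannot be negative; such high-``f`` nodes
    are almost always obstacles anyway).

    Parameters
    ----------
    f : float or ndarray
        Local fibrosis level in percent, in [0, 100].

    Returns
    -------
    RemodelingFactors (scalar input) or tuple of arrays (array input).
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0) or np.any(f_arr > 100):
        raise ValueError("fibrosis percentage must lie in [0, 100]")
    s_na = np.maximum(0.0, 1.0 - 1.55 * f_arr / 100.0)
    s_kr = np.maximum(0.0, 1.0 - 1.75 * f_arr / 100.0)
    s_ks = np.maximum(0.0, 1.0 - 2.0 * f_arr / 100.0)
    if np.isscalar(f) or f_arr.ndim == 0:
        return RemodelingFactors(float(s_na), float(s_kr), float(s_ks))
    return s_na, s_kr, s_ks


def apply_remodeling(f: float, base: CellParams) -> CellParams:
    """Return a copy of ``base`` with I_Na/I_Kr/I_Ks conductances scaled
    according to the local fibrosis percentage ``f``.  All other parameters
    are untouched."""
    s = remodeling_factors(float(f))
    return replace(base, g_na=base.g_na * s.s_na,
                   g_kr=base.g_kr * s.s_kr, g_ks=base.g_ks * s.s_ks)


def resting_state(n: int = 1, dtype=np.float64) -> np.ndarray:
    """TP06 resting state, shape ``(N_STATE, n)``.

    These are the published initial conditions; they are within the model's
    resting basin and relax to the true fixed point within a few hundred ms.
    """
    y0 = {
        "V": -86.2, "m": 0.0, "h": 0.75, "j": 0.75,
        "xr1": 0.0, "xr2": 1.0, "xs": 0.0, "r": 0.0, "s": 1.0,
        "d": 0.0, "f": 1.0, "f2": 1.0, "fcass": 1.0, "rr": 1.0,
        "cai": 0.00007, "casr": 1.3, "cass": 0.00007,
        "nai": 7.67, "ki": 138.3,
    }
    y = np.empty((N_STATE, n), dtype=dtype)
    for name, k in IDX.items():
        y[k, :] = y0[name]
    return y


# ---------------------------------------------------------------------------
# Gate kinetics
# ---------------------------------------------------------------------------

def gate_tables(V, params: CellParams):
    """Steady states and time constants of all voltage-dependent gates.

    Returns a dict ``{gate: (inf, tau)}`` evaluated element-wise on ``V``
    (mV).  ``fcass`` is calcium-dependent and handled separately.
    """
    V = np.asarray(V, dtype=float)
    out = {}

    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    b_m = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    out["m"] = (m_inf, a_m * b_m)

    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    a_h = np.where(V >= -40.0, 0.0, 0.057 * np.exp(-(V + 80.0) / 6.8))
    b_h = np.where(
        V >= -40.0,
        0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
        2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
    )
    out["h"] = (h_inf, 1.0 / (a_h + b_h))

    a_j = np.where(
        V >= -40.0,
        0.0,
        (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
    )
    b_j = np.where(
        V >= -40.0,
        0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
        0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
    )
    out["j"] = (h_inf, 1.0 / (a_j + b_j))  # j_inf == h_inf in TP06

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    a = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    b = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    out["xr1"] = (xr1_inf, a * b)

    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    a = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    b = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    out["xr2"] = (xr2_inf, a * b)

    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    a = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    b = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    out["xs"] = (xs_inf, a * b + 80.0)

    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    out["r"] = (r_inf, 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8)

    # s gate is transmural-type dependent
    if params.variant == "endo":
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)
    out["s"] = (s_inf, tau_s)

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    a = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    b = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    c = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    out["d"] = (d_inf, a * b + c)

    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    out["f"] = (f_inf, tau_f * params.tau_f_scale)

    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    out["f2"] = (f2_inf, tau_f2 * params.tau_f2_scale)

    return out


def _fcass_kinetics(cass):
    ratio = (cass / 0.05) ** 2
    inf = 0.6 / (1.0 + ratio) + 0.4
    tau = 80.0 / (1.0 + ratio) + 2.0
    return inf, tau


# ---------------------------------------------------------------------------
# Currents
# ---------------------------------------------------------------------------

def _check_finite(y: np.ndarray) -> None:
    if not np.all(np.isfinite(y)):
        bad = np.where(~np.isfinite(y))
        name = STATE_NAMES[int(bad[0][0])]
        raise FloatingPointError(f"non-finite state variable {name!r} (first at cell index {int(bad[1][0]) if y.ndim > 1 else 0})")


def compute_currents(y: np.ndarray, params: CellParams, stim=0.0) -> Dict[str, np.ndarray]:
    """All TP06 membrane currents (pA/pF) for state array ``y`` of shape
    ``(N_STATE, n)``.  Returns a dict including the total ``"i_ion"``
    (stimulus excluded)."""
    p = params
    V = y[IDX["V"]]
    m, h, j = y[IDX["m"]], y[IDX["h"]], y[IDX["j"]]
    xr1, xr2, xs = y[IDX["xr1"]], y[IDX["xr2"]], y[IDX["xs"]]
    r, s = y[IDX["r"]], y[IDX["s"]]
    d, f, f2, fcass = y[IDX["d"]], y[IDX["f"]], y[IDX["f2"]], y[IDX["fcass"]]
    cai, cass = y[IDX["cai"]], y[IDX["cass"]]
    nai, ki = y[IDX["nai"]], y[IDX["ki"]]

    e_k = RTONF * np.log(p.ko / ki)
    e_na = RTONF * np.log(p.nao / nai)
    e_ks = RTONF * np.log((p.ko + p.p_kna * p.nao) / (ki + p.p_kna * nai))
    e_ca = 0.5 * RTONF * np.log(p.cao / cai)

    out = {}
    out["i_na"] = p.g_na * m ** 3 * h * j * (V - e_na)

    vf_rt = V * FARADAY / (R_GAS * TEMP)
    z = 2.0 * (V - 15.0) * FARADAY / (R_GAS * TEMP)
    # limit z -> 0 handled by series expansion of z/(exp(z)-1)
    zsafe = np.where(np.abs(z) < 1e-7, 1e-7, z)
    denom = np.expm1(zsafe)
    pref = p.g_cal * d * f * f2 * fcass * 2.0 * FARADAY * zsafe / denom
    out["i_cal"] = pref * (0.25 * np.exp(zsafe) * cass - p.cao)

    sqrt_ko = np.sqrt(p.ko / 5.4)
    out["i_to"] = p.g_to * r * s * (V - e_k)
    out["i_kr"] = p.g_kr * sqrt_ko * xr1 * xr2 * (V - e_k)
    out["i_ks"] = p.g_ks * xs ** 2 * (V - e_ks)

    u = V - e_k
    a_k1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    b_k1 = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (1.0 + np.exp(-0.5 * u))
    out["i_k1"] = p.g_k1 * sqrt_ko * a_k1 / (a_k1 + b_k1) * u

    e1 = np.exp(p.gamma * vf_rt)
    e2 = np.exp((p.gamma - 1.0) * vf_rt)
    out["i_naca"] = (p.k_naca
                     * (e1 * nai ** 3 * p.cao - e2 * p.nao ** 3 * cai * p.alpha_naca)
                     / ((p.km_nai ** 3 + p.nao ** 3) * (p.km_ca + p.cao)
                        * (1.0 + p.k_sat * e2)))

    rec_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vf_rt) + 0.0353 * np.exp(-vf_rt))
    out["i_nak"] = p.k_nak * (p.ko / (p.ko + p.km_k)) * (nai / (nai + p.km_na)) * rec_nak

    out["i_pca"] = p.g_pca * cai / (p.kp_ca + cai)
    out["i_pk"] = p.g_pk * (V - e_k) / (1.0 + np.exp((25.0 - V) / 5.98))
    out["i_bna"] = p.g_bna * (V - e_na)
    out["i_bca"] = p.g_bca * (V - e_ca)

    out["i_ion"] = (out["i_na"] + out["i_cal"] + out["i_to"] + out["i_kr"]
                    + out["i_ks"] + out["i_k1"] + out["i_naca"] + out["i_nak"]
                    + out["i_pca"] + out["i_pk"] + out["i_bna"] + out["i_bca"])
    return out


def ionic_total_current(y: np.ndarray, params: CellParams, stim=0.0):
    """Total ionic current and time-derivatives of all non-voltage states.

    The calcium concentrations use the rapid-buffering (instantaneous buffer
    equilibrium) form, so the returned derivatives are those of the *free*
    concentrations.

    Parameters
    ----------
    y : ndarray, shape (N_STATE,) or (N_STATE, n)
    params : CellParams
    stim : stimulus current (pA/pF) entering the K+ balance, as in TP06.

    Returns
    -------
    i_ion : total ionic current (pA/pF), positive = outward
    derivs : dict name -> d(state)/dt (1/ms or mM/ms)
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != N_STATE:
        y = y.T
    _check_finite(y)
    p = params
    cur = compute_currents(y, p)
    V = y[IDX["V"]]
    gates = gate_tables(V, p)
    derivs = {}
    for g in _GATES:
        inf, tau = gates[g]
        derivs[g] = (inf - y[IDX[g]]) / tau
    cass = y[IDX["cass"]]
    inf, tau = _fcass_kinetics(cass)
    derivs["fcass"] = (inf - y[IDX["fcass"]]) / tau

    cai, casr = y[IDX["cai"]], y[IDX["casr"]]
    rr = y[IDX["rr"]]
    k_casr = p.max_sr - (p.max_sr - p.min_sr) / (1.0 + (p.ec_sr / casr) ** 2)
    k1 = p.k1_rel / k_casr
    k2 = p.k2_rel * k_casr
    derivs["rr"] = p.k4_rel * (1.0 - rr) - k2 * cass * rr
    oo = k1 * cass ** 2 * rr / (p.k3_rel + k1 * cass ** 2)
    i_rel = p.v_rel * oo * (casr - cass)
    i_leak = p.v_leak * (casr - cai)
    i_up = p.v_maxup / (1.0 + p.k_up ** 2 / cai ** 2)
    i_xfer = p.v_xfer * (cass - cai)

    cap = p.capacitance
    inv_vc_f2 = 1.0 / (2.0 * p.v_c * FARADAY)
    inv_vc_f = 1.0 / (p.v_c * FARADAY)
    inv_vss_f2 = 1.0 / (2.0 * p.v_ss * FARADAY)

    # rapid buffering factors beta = 1 / (1 + B*K/(c+K)^2)
    beta_c = 1.0 / (1.0 + p.buf_c * p.k_buf_c / (cai + p.k_buf_c) ** 2)
    beta_sr = 1.0 / (1.0 + p.buf_sr * p.k_buf_sr / (casr + p.k_buf_sr) ** 2)
    beta_ss = 1.0 / (1.0 + p.buf_ss * p.k_buf_ss / (cass + p.k_buf_ss) ** 2)

    j_cai = (-(cur["i_bca"] + cur["i_pca"] - 2.0 * cur["i_naca"]) * inv_vc_f2 * cap
             - (i_up - i_leak) * (p.v_sr / p.v_c) + i_xfer)
    j_casr = i_up - i_rel - i_leak
    j_cass = (-i_xfer * (p.v_c / p.v_ss) + i_rel * (p.v_sr / p.v_ss)
              - cur["i_cal"] * inv_vss_f2 * cap)
    derivs["cai"] = beta_c * j_cai
    derivs["casr"] = beta_sr * j_casr
    derivs["cass"] = beta_ss * j_cass

    derivs["nai"] = -(cur["i_na"] + cur["i_bna"]
                      + 3.0 * cur["i_nak"] + 3.0 * cur["i_naca"]) * inv_vc_f * cap
    derivs["ki"] = -(-np.asarray(stim) + cur["i_k1"] + cur["i_to"] + cur["i_kr"]
                     + cur["i_ks"] - 2.0 * cur["i_nak"] + cur["i_pk"]) * inv_vc_f * cap
    i_ion = cur["i_ion"]
    if i_ion.size == 1:
        i_ion = float(i_ion[0])
        derivs = {k: float(np.asarray(v).ravel()[0]) for k, v in derivs.items()}
    return i_ion, derivs


def step_cell(y: np.ndarray, params: CellParams, dt: float, stim=0.0) -> np.ndarray:
    """One time step of the full TP06 model (no diffusion).

    Uses the same update scheme as the original TP06 implementation:
    explicit Euler for V and the ion concentrations, the Rush-Larsen
    exponential update for the Hodgkin-Huxley gates (whose fastest time
    constant, tau_m ~ 1 us at rest, is far below any practical step), and
    the algebraic rapid-buffering projection for the three calcium pools.
    ``stim`` (pA/pF, positive = depolarizing) may be a scalar or per-cell
    array.

    Returns a new state array; ``y`` is not modified.
    """
    p = params
    y = np.asarray(y, dtype=float)
    out = y.copy()
    V = y[IDX["V"]]
    cur = compute_currents(y, p)

    gates = gate_tables(V, p)
    for g in _GATES:
        inf, tau = gates[g]
        out[IDX[g]] = inf - (inf - y[IDX[g]]) * np.exp(-dt / tau)
    inf, tau = _fcass_kinetics(y[IDX["cass"]])
    out[IDX["fcass"]] = y[IDX["fcass"]] + dt * (inf - y[IDX["fcass"]]) / tau

    cai, casr, cass = y[IDX["cai"]], y[IDX["casr"]], y[IDX["cass"]]
    rr = y[IDX["rr"]]
    k_casr = p.max_sr - (p.max_sr - p.min_sr) / (1.0 + (p.ec_sr / casr) ** 2)
    k1 = p.k1_rel / k_casr
    k2 = p.k2_rel * k_casr
    out[IDX["rr"]] = rr + dt * (p.k4_rel * (1.0 - rr) - k2 * cass * rr)
    oo = k1 * cass ** 2 * rr / (p.k3_rel + k1 * cass ** 2)
    i_rel = p.v_rel * oo * (casr - cass)
    i_leak = p.v_leak * (casr - cai)
    i_up = p.v_maxup / (1.0 + p.k_up ** 2 / cai ** 2)
    i_xfer = p.v_xfer * (cass - cai)

    cap = p.capacitance
    inv_vc_f2 = 1.0 / (2.0 * p.v_c * FARADAY)
    inv_vc_f = 1.0 / (p.v_c * FARADAY)
    inv_vss_f2 = 1.0 / (2.0 * p.v_ss * FARADAY)

    # SR pool with instantaneous calsequestrin buffering
    ca_csqn = p.buf_sr * casr / (casr + p.k_buf_sr)
    d_casr = dt * (i_up - i_rel - i_leak)
    b = p.buf_sr - ca_csqn - d_casr - casr + p.k_buf_sr
    c = p.k_buf_sr * (ca_csqn + d_casr + casr)
    out[IDX["casr"]] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    ca_ssbuf = p.buf_ss * cass / (cass + p.k_buf_ss)
    d_cass = dt * (-i_xfer * (p.v_c / p.v_ss) + i_rel * (p.v_sr / p.v_ss)
                   - cur["i_cal"] * inv_vss_f2 * cap)
    b = p.buf_ss - ca_ssbuf - d_cass - cass + p.k_buf_ss
    c = p.k_buf_ss * (ca_ssbuf + d_cass + cass)
    out[IDX["cass"]] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    ca_buf = p.buf_c * cai / (cai + p.k_buf_c)
    d_cai = dt * (-(cur["i_bca"] + cur["i_pca"] - 2.0 * cur["i_naca"]) * inv_vc_f2 * cap
                  - (i_up - i_leak) * (p.v_sr / p.v_c) + i_xfer)
    b = p.buf_c - ca_buf - d_cai - cai + p.k_buf_c
    c = p.k_buf_c * (ca_buf + d_cai + cai)
    out[IDX["cai"]] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    out[IDX["nai"]] = y[IDX["nai"]] - dt * (cur["i_na"] + cur["i_bna"]
                                            + 3.0 * cur["i_nak"] + 3.0 * cur["i_naca"]) * inv_vc_f * cap
    out[IDX["ki"]] = y[IDX["ki"]] - dt * (-stim + cur["i_k1"] + cur["i_to"] + cur["i_kr"]
                                          + cur["i_ks"] - 2.0 * cur["i_nak"] + cur["i_pk"]) * inv_vc_f * cap

    out[IDX["V"]] = V + dt * (-cur["i_ion"] + stim)
    return out
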