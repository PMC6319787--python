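"""JIT-compiled forward-Euler kernels for TP06 tissue integration.

The tissue update is the performance-critical path: the monodomain-style
discrete equation

    C_m dV_i/dt = sum_j eta_ij g_gap (V_j - V_i) - I_ion(V_i, ...)

is advanced with explicit Euler at a fixed time step (0.02 ms by default) on
up to ~10^5 coupled nodes for tens of simulated seconds.  To make this
tractable on one CPU core, all voltage-dependent terms of the TP06 right-hand
side (gate steady states / time constants folded into per-step update
coefficients, the L-type-calcium and Na/Ca-exchanger driving terms, pump
rectification factors and the inward-rectifier curve) are pre-tabulated on a
0.05 mV voltage grid and linearly interpolated inside a numba kernel.

Obstacle (fibroblast) nodes carry no state: the kernel only sees the
*compressed* array of myocyte nodes plus a (n, 4) neighbor-index table with
-1 marking an uncoupled edge, which makes no-flux boundaries and uncoupled
obstacles the same thing.

Reversal potentials change on the time scale of seconds (intracellular ion
drift), so they are refreshed only every ``e_stride`` steps (0.5 ms by
default) to keep the four logarithms out of the per-step cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import tp06
from .tp06 import IDX, N_STATE, RTONF, FARADAY, R_GAS, TEMP, _GATES

__all__ = ["TableSet", "build_tables", "step_chunk", "refresh_reversals"]

# Voltage grid for the lookup tables
V_MIN, V_MAX, DV = -120.0, 80.0, 0.05
# Grid in u = V - E_K for the inward rectifier
U_MIN, U_MAX, DU = -80.0, 220.0, 0.05

# Table row indices: gate A coefficients in rows [0, 11), gate B coefficients
# in rows [11, 22) (blocked so the in-kernel gate loop reads contiguous
# spans), then the voltage-only current factors.
N_GATE = len(_GATES)
T_CALA = 2 * N_GATE
T_CALB = T_CALA + 1
T_NACAP = T_CALA + 2
T_NACAM = T_CALA + 3
T_NAK = T_CALA + 4
T_PK = T_CALA + 5
N_TABLES = T_PK + 1

# Indices into the packed scalar-constants tuple
(C_GTO, C_GPCA, C_KPCA, C_GBNA, C_GBCA, C_KMNA, C_CAP,
 C_IVCF, C_IVCF2, C_IVSSF2, C_VREL, C_K1R, C_K2R, C_K3R, C_K4R,
 C_ECSR, C_MAXSR, C_MINSR, C_VLEAK, C_VXFER, C_VMAXUP, C_KUP,
 C_BUFC, C_KBUFC, C_BUFSR, C_KBUFSR, C_BUFSS, C_KBUFSS,
 C_VSRVC, C_VCVSS, C_VSRVSS, C_NAO, C_KO, C_CAO, C_PKNA) = range(35)


@dataclass
class TableSet:
    """Lookup tables and packed constants for one (params, dt) combination."""

    tb: np.ndarray        # (n_v, N_TABLES); transposed so one node's lookups share cache lines
    k1: np.ndarray        # inward-rectifier current vs (V - E_K)
    consts: np.ndarray    # scalar constants, indexed by C_* above
    dt: float
    dtype: np.dtype

    @property
    def n_v(self) -> int:
        return self.tb.shape[0]


def build_tables(params: tp06.CellParams, dt: float, dtype=np.float32) -> TableSet:
    """Precompute the voltage tables of the TP06 right-hand side.

    The per-step gate update ``g <- A(V) g + B(V)`` embeds ``dt`` via the
    Rush-Larsen exponential scheme: ``A = exp(-dt/tau)``, ``B = g_inf (1 -
    A)``.  (The fastest TP06 gate, m, has tau ~ 1 us at rest, far below the
    0.02 ms step, so explicit Euler on the gates is unstable; the exponential
    update is exact for the locally linear gate equation and is what the
    published TP06 implementations use.)
    """
    p = params
    v = np.arange(V_MIN, V_MAX + DV / 2, DV, dtype=np.float64)
    gates = tp06.gate_tables(v, p)
    tb = np.empty((N_TABLES, v.size), dtype=np.float64)
    for g_i, g in enumerate(_GATES):
        inf, tau = gates[g]
        a = np.exp(-dt / tau)
        tb[g_i] = a
        tb[N_GATE + g_i] = inf * (1.0 - a)

    z = 2.0 * (v - 15.0) * FARADAY / (R_GAS * TEMP)
    zsafe = np.where(np.abs(z) < 1e-7, 1e-7, z)
    ratio = np.where(np.abs(z) < 1e-7, 1.0, zsafe / np.expm1(zsafe))
    pref = p.g_cal * 2.0 * FARADAY * ratio
    tb[T_CALA] = pref * 0.25 * np.exp(z)
    tb[T_CALB] = pref * p.cao

    vf_rt = v * FARADAY / (R_GAS * TEMP)
    e1 = np.exp(p.gamma * vf_rt)
    e2 = np.exp((p.gamma - 1.0) * vf_rt)
    naca_pref = p.k_naca / ((p.km_nai ** 3 + p.nao ** 3) * (p.km_ca + p.cao))
    den = 1.0 + p.k_sat * e2
    tb[T_NACAP] = naca_pref * e1 * p.cao / den
    tb[T_NACAM] = naca_pref * e2 * p.nao ** 3 * p.alpha_naca / den

    tb[T_NAK] = (p.k_nak * (p.ko / (p.ko + p.km_k))
                 / (1.0 + 0.1245 * np.exp(-0.1 * vf_rt) + 0.0353 * np.exp(-vf_rt)))
    tb[T_PK] = p.g_pk / (1.0 + np.exp((25.0 - v) / 5.98))

    u = np.arange(U_MIN, U_MAX + DU / 2, DU, dtype=np.float64)
    a_k1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    b_k1 = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (1.0 + np.exp(-0.5 * u))
    k1 = p.g_k1 * np.sqrt(p.ko / 5.4) * a_k1 / (a_k1 + b_k1) * u

    consts = (
        p.g_to, p.g_pca, p.kp_ca, p.g_bna, p.g_bca, p.km_na, p.capacitance,
        1.0 / (p.v_c * FARADAY), 1.0 / (2.0 * p.v_c * FARADAY),
        1.0 / (2.0 * p.v_ss * FARADAY),
        p.v_rel, p.k1_rel, p.k2_rel, p.k3_rel, p.k4_rel,
        p.ec_sr, p.max_sr, p.min_sr, p.v_leak, p.v_xfer, p.v_maxup, p.k_up,
        p.buf_c, p.k_buf_c, p.buf_sr, p.k_buf_sr, p.buf_ss, p.k_buf_ss,
        p.v_sr / p.v_c, p.v_c / p.v_ss, p.v_sr / p.v_ss,
        p.nao, p.ko, p.cao, p.p_kna,
    )
    return TableSet(tb=np.ascontiguousarray(tb.T).astype(dtype), k1=k1.astype(dtype),
                    consts=np.asarray(consts, dtype=dtype), dt=float(dt),
                    dtype=np.dtype(dtype))


@njit(cache=True, fastmath=True, error_model="numpy")
def refresh_reversals(nai, ki, cai, consts, ena, ek, eks, eca):
    nao = consts[C_NAO]
    ko = consts[C_KO]
    cao = consts[C_CAO]
    pkna = consts[C_PKNA]
    for i in range(nai.shape[0]):
        ena[i] = RTONF * np.log(nao / nai[i])
        ek[i] = RTONF * np.log(ko / ki[i])
        eks[i] = RTONF * np.log((ko + pkna * nao) / (ki[i] + pkna * nai[i]))
        eca[i] = 0.5 * RTONF * np.log(cao / cai[i])


def gates_from_state(S: np.ndarray) -> np.ndarray:
    """Node-major (n, 11) copy of the HH gate block of a (N_STATE, n) state.

    The kernel keeps gates node-major so the per-node 11-gate Rush-Larsen
    update reads and writes one contiguous span.
    """
    return np.ascontiguousarray(S[1:1 + N_GATE].T)


def sync_gates(S: np.ndarray, G: np.ndarray) -> None:
    """Write the kernel's gate array back into the canonical state layout."""
    S[1:1 + N_GATE] = G.T


@njit(cache=True, fastmath=True, error_model="numpy")
def step_chunk(S, G, v_old, jbuf, nbr, gna, gkr, gks, stim,
               ena, ek, eks, eca,
               tb, k1tab, consts, dt, k_coup, n_steps, e_stride):
    """Advance all myocyte nodes ``n_steps`` time steps in place.

    Explicit Euler for V and the ion concentrations, Rush-Larsen (via the A/B
    tables) for the HH gates.  Two passes per step: a scalar pass with the
    table gathers (gates, membrane currents, coupling, V update) that stores
    the four ionic fluxes the slow subsystem needs into ``jbuf``, and a
    branch-free vectorizable pass for the calcium pools and Na+/K+ balance.

    ``S`` is the (N_STATE, n) state array (its gate rows are stale while the
    caller holds ``G``; see :func:`sync_gates`); ``G`` the (n, 11) node-major
    gate array; ``nbr`` the (n, 4) neighbor table (indices into the
    compressed node list, -1 = uncoupled edge); ``gna``/``gkr``/``gks``
    per-node peak conductances (remodeling included, sqrt(Ko/5.4) folded into
    ``gkr``); ``stim`` a per-node current (pA/pF, positive depolarizing) held
    constant over the chunk; ``k_coup = g_gap / C_m`` in 1/ms.
    """
    V = S[0]
    fcass = S[12]; rr = S[13]
    cai = S[14]; casr = S[15]; cass = S[16]
    nai = S[17]; ki = S[18]
    j_cal = jbuf[0]; j_cam = jbuf[1]; j_na = jbuf[2]; j_k = jbuf[3]

    n = V.shape[0]
    inv_dv = 1.0 / DV
    inv_du = 1.0 / DU
    nv = tb.shape[0]
    nu = k1tab.shape[0]

    g_to = consts[C_GTO]; g_pca = consts[C_GPCA]; kp_ca = consts[C_KPCA]
    g_bna = consts[C_GBNA]; g_bca = consts[C_GBCA]; km_na = consts[C_KMNA]
    cap = consts[C_CAP]
    inv_vc_f = consts[C_IVCF]; inv_vc_f2 = consts[C_IVCF2]
    inv_vss_f2 = consts[C_IVSSF2]
    v_rel = consts[C_VREL]
    k2r = consts[C_K2R]; k4r = consts[C_K4R]
    max_sr = consts[C_MAXSR]; min_sr = consts[C_MINSR]
    v_leak = consts[C_VLEAK]; v_xfer = consts[C_VXFER]
    v_maxup = consts[C_VMAXUP]; k_up = consts[C_KUP]
    buf_c = consts[C_BUFC]; k_buf_c = consts[C_KBUFC]
    buf_sr = consts[C_BUFSR]; k_buf_sr = consts[C_KBUFSR]
    buf_ss = consts[C_BUFSS]; k_buf_ss = consts[C_KBUFSS]
    vsr_vc = consts[C_VSRVC]; vc_vss = consts[C_VCVSS]; vsr_vss = consts[C_VSRVSS]
    ec2 = consts[C_ECSR] * consts[C_ECSR]
    dsr = max_sr - min_sr
    kup2 = k_up * k_up
    # k3/k1' combined so the open-probability denominator needs one division
    k3k1 = consts[C_K3R] / consts[C_K1R]

    for step in range(n_steps):
        if step % e_stride == 0:
            refresh_reversals(nai, ki, cai, consts, ena, ek, eks, eca)
        for i in range(n):
            v_old[i] = V[i]

        # --- pass 1: gathers, gates, membrane currents, coupling, V ---
        for i in range(n):
            v_i = v_old[i]

            cp = 0.0
            for q in range(4):
                nb = nbr[i, q]
                if nb >= 0:
                    cp += v_old[nb] - v_i

            tv = (v_i - V_MIN) * inv_dv
            if tv < 0.0:
                tv = 0.0
            elif tv > nv - 1.001:
                tv = nv - 1.001
            i0 = int(tv)
            w = tv - i0

            tu = (v_i - ek[i] - U_MIN) * inv_du
            if tu < 0.0:
                tu = 0.0
            elif tu > nu - 1.001:
                tu = nu - 1.001
            j0 = int(tu)
            wu = tu - j0

            t0 = tb[i0]
            t1 = tb[i0 + 1]

            # currents from pre-update gate values
            m_g = G[i, 0]; h_g = G[i, 1]; j_g = G[i, 2]
            i_na = gna[i] * m_g * m_g * m_g * h_g * j_g * (v_i - ena[i])
            cal_a = t0[T_CALA] + w * (t1[T_CALA] - t0[T_CALA])
            cal_b = t0[T_CALB] + w * (t1[T_CALB] - t0[T_CALB])
            i_cal = G[i, 8] * G[i, 9] * G[i, 10] * fcass[i] * (cal_a * cass[i] - cal_b)
            i_to = g_to * G[i, 6] * G[i, 7] * (v_i - ek[i])
            i_kr = gkr[i] * G[i, 3] * G[i, 4] * (v_i - ek[i])
            i_ks = gks[i] * G[i, 5] * G[i, 5] * (v_i - eks[i])
            i_k1 = k1tab[j0] + wu * (k1tab[j0 + 1] - k1tab[j0])
            nacap = t0[T_NACAP] + w * (t1[T_NACAP] - t0[T_NACAP])
            nacam = t0[T_NACAM] + w * (t1[T_NACAM] - t0[T_NACAM])
            i_naca = nacap * nai[i] * nai[i] * nai[i] - nacam * cai[i]
            nakf = t0[T_NAK] + w * (t1[T_NAK] - t0[T_NAK])
            i_nak = nakf * nai[i] / (nai[i] + km_na)
            i_pca = g_pca * cai[i] / (kp_ca + cai[i])
            pkf = t0[T_PK] + w * (t1[T_PK] - t0[T_PK])
            i_pk = pkf * (v_i - ek[i])
            i_bna = g_bna * (v_i - ena[i])
            i_bca = g_bca * (v_i - eca[i])

            i_ion = (i_na + i_cal + i_to + i_kr + i_ks + i_k1 + i_naca
                     + i_nak + i_pca + i_pk + i_bna + i_bca)

            # Rush-Larsen gate update; contiguous A/B blocks vectorize
            for g in range(N_GATE):
                a = t0[g] + w * (t1[g] - t0[g])
                b = t0[N_GATE + g] + w * (t1[N_GATE + g] - t0[N_GATE + g])
                G[i, g] = a * G[i, g] + b

            j_cal[i] = i_cal
            j_cam[i] = i_bca + i_pca - 2.0 * i_naca
            j_na[i] = i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca
            j_k[i] = -stim[i] + i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk

            V[i] = v_i + dt * (k_coup * cp - i_ion + stim[i])

        # --- pass 2: calcium subsystem and Na+/K+ balance (branch-free) ---
        for i in range(n):
            # Ca-subspace inactivation gate
            fr = cass[i] * 20.0
            fr = fr * fr
            invf = 1.0 / (1.0 + fr)
            fc_inf = 0.6 * invf + 0.4
            fc_tau = 80.0 * invf + 2.0
            fcass[i] = fcass[i] + dt * (fc_inf - fcass[i]) / fc_tau

            # SR release (RyR with calsequestrin-dependent gating)
            casr2 = casr[i] * casr[i]
            k_casr = max_sr - dsr * casr2 / (casr2 + ec2)
            rr[i] = rr[i] + dt * (k4r * (1.0 - rr[i]) - k2r * k_casr * cass[i] * rr[i])
            cass2 = cass[i] * cass[i]
            oo = cass2 * rr[i] / (k3k1 * k_casr + cass2)
            i_rel = v_rel * oo * (casr[i] - cass[i])
            i_leak = v_leak * (casr[i] - cai[i])
            cai2 = cai[i] * cai[i]
            i_up = v_maxup * cai2 / (cai2 + kup2)
            i_xfer = v_xfer * (cass[i] - cai[i])

            # pools with instantaneous (algebraic) buffering
            ca_csqn = buf_sr * casr[i] / (casr[i] + k_buf_sr)
            d_casr = dt * (i_up - i_rel - i_leak)
            bb = buf_sr - ca_csqn - d_casr - casr[i] + k_buf_sr
            cc = k_buf_sr * (ca_csqn + d_casr + casr[i])
            casr[i] = (np.sqrt(bb * bb + 4.0 * cc) - bb) * 0.5

            ca_ssbuf = buf_ss * cass[i] / (cass[i] + k_buf_ss)
            d_cass = dt * (-i_xfer * vc_vss + i_rel * vsr_vss - j_cal[i] * inv_vss_f2 * cap)
            bb = buf_ss - ca_ssbuf - d_cass - cass[i] + k_buf_ss
            cc = k_buf_ss * (ca_ssbuf + d_cass + cass[i])
            cass[i] = (np.sqrt(bb * bb + 4.0 * cc) - bb) * 0.5

            ca_buf = buf_c * cai[i] / (cai[i] + k_buf_c)
            d_cai = dt * (-j_cam[i] * inv_vc_f2 * cap - (i_up - i_leak) * vsr_vc + i_xfer)
            bb = buf_c - ca_buf - d_cai - cai[i] + k_buf_c
            cc = k_buf_c * (ca_buf + d_cai + cai[i])
            cai[i] = (np.sqrt(bb * bb + 4.0 * cc) - bb) * 0.5

            nai[i] = nai[i] - dt * j_na[i] * inv_vc_f * cap
            ki[i] = ki[i] - dt * j_k[i] * inv_vc_f * cap
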