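"""Independent reference implementation of the TP06 ventricular myocyte model.

Used only as a test oracle.  Deliberately written from the published model
equations in plain scalar style — no lookup tables, no Rush-Larsen scheme
(explicit Euler for every variable at a small step dt <= 0.002 ms, below the
stability limit of the fastest gate), no code shared with the package's
implementation.  Calcium buffering uses the same algebraic rapid-buffering
projection as the published model code.

State vector order matches the package's STATE_NAMES so tests can compare
states directly.
"""

import numpy as np
from numba import njit

# state indices: V m h j xr1 xr2 xs r s d f f2 fcass rr cai casr cass nai ki

EPI = 0
ENDO = 1
MCELL = 2


@njit(cache=True)
def reference_step(y, dt, stim, cell_type):
    """One explicit-Euler step; returns a new state array."""
    R = 8314.472
    F = 96485.3415
    T = 310.0
    rtonf = R * T / F

    ko, nao, cao = 5.4, 140.0, 2.0
    g_na, g_k1, g_kr = 14.838, 5.405, 0.153
    if cell_type == MCELL:
        g_ks, g_to = 0.098, 0.294
    elif cell_type == ENDO:
        g_ks, g_to = 0.392, 0.073
    else:
        g_ks, g_to = 0.392, 0.294
    g_cal = 3.980e-5
    g_bna, g_bca = 0.00029, 0.000592
    g_pca, g_pk = 0.1238, 0.0146
    p_nak, km_k, km_na = 2.724, 1.0, 40.0
    k_naca, km_nai, km_ca, k_sat, gam, alp = 1000.0, 87.5, 1.38, 0.1, 0.35, 2.5
    kp_ca, p_kna = 0.0005, 0.03
    v_maxup, k_up = 0.006375, 0.00025
    v_rel, k1p, k2p, k3, k4 = 0.102, 0.15, 0.045, 0.060, 0.005
    ec, max_sr, min_sr = 1.5, 2.5, 1.0
    v_leak, v_xfer = 0.00036, 0.0038
    buf_c, k_buf_c = 0.2, 0.001
    buf_sr, k_buf_sr = 10.0, 0.3
    buf_ss, k_buf_ss = 0.4, 0.00025
    vc, vsr, vss, cap = 0.016404, 0.001094, 0.00005468, 0.185

    out = y.copy()
    V = y[0]
    m, h, jg = y[1], y[2], y[3]
    xr1, xr2, xs = y[4], y[5], y[6]
    rg, sg = y[7], y[8]
    d, fg, f2, fcass = y[9], y[10], y[11], y[12]
    rr, cai, casr, cass = y[13], y[14], y[15], y[16]
    nai, ki = y[17], y[18]

    e_k = rtonf * np.log(ko / ki)
    e_na = rtonf * np.log(nao / nai)
    e_ks = rtonf * np.log((ko + p_kna * nao) / (ki + p_kna * nai))
    e_ca = 0.5 * rtonf * np.log(cao / cai)

    i_na = g_na * m ** 3 * h * jg * (V - e_na)
    zz = 2.0 * (V - 15.0) * F / (R * T)
    if abs(zz) < 1e-9:
        zz = 1e-9
    i_cal = (g_cal * d * fg * f2 * fcass * 4.0 * (V - 15.0) * F * F / (R * T)
             * (0.25 * cass * np.exp(zz) - cao) / (np.exp(zz) - 1.0))
    i_to = g_to * rg * sg * (V - e_k)
    i_kr = g_kr * np.sqrt(ko / 5.4) * xr1 * xr2 * (V - e_k)
    i_ks = g_ks * xs * xs * (V - e_ks)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - e_k - 200.0)))
    bk1 = ((3.0 * np.exp(0.0002 * (V - e_k + 100.0))
            + np.exp(0.1 * (V - e_k - 10.0)))
           / (1.0 + np.exp(-0.5 * (V - e_k))))
    i_k1 = g_k1 * ak1 / (ak1 + bk1) * (V - e_k)
    vfrt = V * F / (R * T)
    i_naca = (k_naca
              * (np.exp(gam * vfrt) * nai ** 3 * cao
                 - np.exp((gam - 1.0) * vfrt) * nao ** 3 * cai * alp)
              / ((km_nai ** 3 + nao ** 3) * (km_ca + cao)
                 * (1.0 + k_sat * np.exp((gam - 1.0) * vfrt))))
    i_nak = (p_nak * (ko / (ko + km_k)) * (nai / (nai + km_na))
             / (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt)))
    i_pca = g_pca * cai / (kp_ca + cai)
    i_pk = g_pk * (V - e_k) / (1.0 + np.exp((25.0 - V) / 5.98))
    i_bna = g_bna * (V - e_na)
    i_bca = g_bca * (V - e_ca)

    i_ion = (i_na + i_cal + i_to + i_kr + i_ks + i_k1 + i_naca + i_nak
             + i_pca + i_pk + i_bna + i_bca)

    # gate kinetics
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau_m = am * bm
    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    tau_xr1 = (450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
               * 6.0 / (1.0 + np.exp((V + 30.0) / 11.5)))
    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    tau_xr2 = (3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
               * 1.12 / (1.0 + np.exp((V - 60.0) / 20.0)))
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    tau_xs = (1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
              * 1.0 / (1.0 + np.exp((V - 35.0) / 15.0)) + 80.0)
    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    if cell_type == ENDO:
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * np.exp(-(V + 45.0) ** 2 / 320.0)
                 + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    tau_d = ((1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25)
             * 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
             + 1.0 / (1.0 + np.exp((50.0 - V) / 20.0)))
    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-(V + 27.0) ** 2 / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-(V + 27.0) ** 2 / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    out[1] = m + dt * (m_inf - m) / tau_m
    out[2] = h + dt * (h_inf - h) / tau_h
    out[3] = jg + dt * (h_inf - jg) / tau_j
    out[4] = xr1 + dt * (xr1_inf - xr1) / tau_xr1
    out[5] = xr2 + dt * (xr2_inf - xr2) / tau_xr2
    out[6] = xs + dt * (xs_inf - xs) / tau_xs
    out[7] = rg + dt * (r_inf - rg) / tau_r
    out[8] = sg + dt * (s_inf - sg) / tau_s
    out[9] = d + dt * (d_inf - d) / tau_d
    out[10] = fg + dt * (f_inf - fg) / tau_f
    out[11] = f2 + dt * (f2_inf - f2) / tau_f2
    out[12] = fcass + dt * (fcass_inf - fcass) / tau_fcass

    # calcium dynamics
    k_casr = max_sr - (max_sr - min_sr) / (1.0 + (ec / casr) ** 2)
    kk1 = k1p / k_casr
    kk2 = k2p * k_casr
    out[13] = rr + dt * (k4 * (1.0 - rr) - kk2 * cass * rr)
    oo = kk1 * cass * cass * out[13] / (k3 + kk1 * cass * cass)
    i_rel = v_rel * oo * (casr - cass)
    i_leak = v_leak * (casr - cai)
    i_up = v_maxup / (1.0 + (k_up / cai) ** 2)
    i_xfer = v_xfer * (cass - cai)

    csqn = buf_sr * casr / (casr + k_buf_sr)
    dd = dt * (i_up - i_rel - i_leak)
    b = buf_sr - csqn - dd - casr + k_buf_sr
    c = k_buf_sr * (csqn + dd + casr)
    out[15] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    ssbuf = buf_ss * cass / (cass + k_buf_ss)
    dd = dt * (-i_xfer * (vc / vss) + i_rel * (vsr / vss)
               - i_cal * cap / (2.0 * vss * F))
    b = buf_ss - ssbuf - dd - cass + k_buf_ss
    c = k_buf_ss * (ssbuf + dd + cass)
    out[16] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    cbuf = buf_c * cai / (cai + k_buf_c)
    dd = dt * (-(i_bca + i_pca - 2.0 * i_naca) * cap / (2.0 * vc * F)
               - (i_up - i_leak) * (vsr / vc) + i_xfer)
    b = buf_c - cbuf - dd - cai + k_buf_c
    c = k_buf_c * (cbuf + dd + cai)
    out[14] = (np.sqrt(b * b + 4.0 * c) - b) / 2.0

    out[17] = nai - dt * (i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * cap / (vc * F)
    out[18] = ki - dt * (-stim + i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk) * cap / (vc * F)

    out[0] = V + dt * (-i_ion + stim)
    return out


@njit(cache=True)
def reference_run(y0, dt, duration, stim_start, stim_dur, stim_amp,
                  record_every, cell_type):
    """Integrate one cell; returns (t, V) sampled every ``record_every`` ms."""
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    n_rec = n_steps // rec_stride + 1
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    y = y0.copy()
    t_out[0] = 0.0
    v_out[0] = y[0]
    k = 1
    for s in range(1, n_steps + 1):
        t = (s - 1) * dt
        stim = stim_amp if (stim_start <= t < stim_start + stim_dur) else 0.0
        y = reference_step(y, dt, stim, cell_type)
        if s % rec_stride == 0:
            t_out[k] = s * dt
            v_out[k] = y[0]
            k += 1
    return t_out[:k], v_out[:k], y


def reference_resting_state():
    y = np.array([-86.2, 0.0, 0.75, 0.75, 0.0, 1.0, 0.0, 0.0, 1.0,
                  0.0, 1.0, 1.0, 1.0, 1.0, 0.00007, 1.3, 0.00007,
                  7.67, 138.3])
    return y


@njit(cache=True)
def reference_step_rl(y, dt, stim, cell_type):
    """Same reference model, but exact exponential (Rush-Larsen) updates for
    the 12 gates so it is stable at the production step of 0.02 ms."""
    out = reference_step(y, dt, stim, cell_type)
    V = y[0]

    def rl(g, inf, tau):
        return inf - (inf - g) * np.exp(-dt / tau)

    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    out[1] = rl(y[1], m_inf, am * bm)
    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah, bh = 0.0, 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    out[2] = rl(y[2], h_inf, 1.0 / (ah + bh))
    if V >= -40.0:
        aj, bj = 0.0, 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    out[3] = rl(y[3], h_inf, 1.0 / (aj + bj))
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    t_xr1 = (450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
             * 6.0 / (1.0 + np.exp((V + 30.0) / 11.5)))
    out[4] = rl(y[4], xr1_inf, t_xr1)
    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    t_xr2 = (3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
             * 1.12 / (1.0 + np.exp((V - 60.0) / 20.0)))
    out[5] = rl(y[5], xr2_inf, t_xr2)
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    t_xs = (1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
            / (1.0 + np.exp((V - 35.0) / 15.0)) + 80.0)
    out[6] = rl(y[6], xs_inf, t_xs)
    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    out[7] = rl(y[7], r_inf, 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8)
    if cell_type == ENDO:
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        t_s = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        t_s = (85.0 * np.exp(-(V + 45.0) ** 2 / 320.0)
               + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)
    out[8] = rl(y[8], s_inf, t_s)
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    t_d = ((1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25)
           * 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
           + 1.0 / (1.0 + np.exp((50.0 - V) / 20.0)))
    out[9] = rl(y[9], d_inf, t_d)
    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    t_f = (1102.5 * np.exp(-(V + 27.0) ** 2 / 225.0)
           + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
           + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    out[10] = rl(y[10], f_inf, t_f)
    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    t_f2 = (562.0 * np.exp(-(V + 27.0) ** 2 / 240.0)
            + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
            + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    out[11] = rl(y[11], f2_inf, t_f2)
    return out


@njit(cache=True)
def reference_cable_run(y0, n_nodes, dt, duration, k_coup,
                        stim_amp, stim_dur, n_stim_nodes, cell_type,
                        record_node, record_every):
    """Brute-force cable integrator: per-node reference steps plus an
    explicit nearest-neighbor coupling sum on the old voltages (no-flux
    ends).  Returns (t, V) at ``record_node``."""
    Y = np.empty((19, n_nodes))
    for i in range(n_nodes):
        Y[:, i] = y0
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_every / dt)))
    t_out = np.empty(n_steps // stride + 1)
    v_out = np.empty(n_steps // stride + 1)
    t_out[0] = 0.0
    v_out[0] = Y[0, record_node]
    k = 1
    for s in range(n_steps):
        t = s * dt
        v_old = Y[0].copy()
        for i in range(n_nodes):
            stim = stim_amp if (t < stim_dur and i < n_stim_nodes) else 0.0
            y_new = reference_step_rl(Y[:, i].copy(), dt, stim, cell_type)
            cp = 0.0
            if i > 0:
                cp += v_old[i - 1] - v_old[i]
            if i < n_nodes - 1:
                cp += v_old[i + 1] - v_old[i]
            y_new[0] = y_new[0] + dt * k_coup * cp
            Y[:, i] = y_new
        if (s + 1) % stride == 0:
            t_out[k] = (s + 1) * dt
            v_out[k] = Y[0, record_node]
            k += 1
    return t_out[:k], v_out[:k]
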