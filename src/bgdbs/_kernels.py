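"""Numba kernels for fixed-step integration of the basal ganglia network.

The Python layer (``cell_models``/``network``) defines the model; these
kernels re-express the same right-hand sides on packed parameter vectors so
the full network can be stepped at dt = 0.01 ms in reasonable time.  A unit
test checks kernel RHS == Python RHS on randomized states.

Parameter vector layouts (built by the ``pack_*`` helpers from the YAML
tables; all kinetics constants flow from ``params/cells.yaml``):

TH   0:Cm 1:gL 2:EL 3:gNa 4:ENa 5:gK 6:EK 7:gT 8:ET 9:bias
     10:m_th 11:m_k 12:h_th 13:h_k 14:h_a0 15:h_ath 16:h_ak 17:h_b0
     18:h_bth 19:h_bk 20:h_phi 21:p_th 22:p_k
     23:r_th 24:r_k 25:r_tau0 26:r_tau1 27:r_thexp 28:r_kexp 29:r_phi

STN  0:Cm 1:gL 2:EL 3:gNa 4:ENa 5:gK 6:EK 7:gCa 8:ECa 9:gT 10:ET 11:bias
     12:m_th 13:m_k 14:h_th 15:h_k 16:h_tau0 17:h_tau1 18:h_tht 19:h_kt
     20:h_phi 21:n_th 22:n_k 23:n_tau0 24:n_tau1 25:n_tht 26:n_kt 27:n_phi
     28:s_th 29:s_k 30:a_th 31:a_k
     32:r_th 33:r_k 34:r_tau0 35:r_tau1 36:r_tht 37:r_kt 38:r_phi

GP   0:Cm 1:gL 2:EL 3:gNa 4:ENa 5:gK 6:EK 7:gCa 8:ECa 9:gT 10:ET 11:bias
     12:m_th 13:m_k 14:h_th 15:h_k 16:h_tau0 17:h_tau1 18:h_tht 19:h_kt
     20:h_phi 21:n_th 22:n_k 23:n_tau0 24:n_tau1 25:n_tht 26:n_kt 27:n_phi
     28:a_th 29:a_k 30:s_th 31:s_k 32:r_th 33:r_k 34:r_tau 35:r_phi

State matrix Y rows (n columns = neurons per population):
     0:V_th 1:h_th 2:r_th | 3:V_stn 4:h_stn 5:n_stn 6:r_stn
     7:V_gpe 8:h_gpe 9:n_gpe 10:r_gpe | 11:V_gpi 12:h_gpi 13:n_gpi 14:r_gpi
     15:s_stn 16:s_gpe 17:s_gpi
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NVAR = 18
V_ROWS = (0, 3, 7, 11)  # TH, STN, GPe, GPi
GATE_ROWS = (1, 2, 4, 5, 6, 8, 9, 10, 12, 13, 14, 15, 16, 17)


# ---------------------------------------------------------------------------
# parameter packing (plain Python; reads the raw YAML dict held by CellParams)


def _g(raw, ch, key):
    return float(raw["channels"][ch][key])


def _kin(raw, gate):
    return raw["gates"][gate]


def pack_th(raw: dict, condition: str) -> np.ndarray:
    g = lambda ch, k: _g(raw, ch, k)
    h = _kin(raw, "h")
    r = _kin(raw, "r")
    return np.array(
        [
            raw["C_m"], g("L", "g_max"), g("L", "E_rev"),
            g("Na", "g_max"), g("Na", "E_rev"), g("K", "g_max"), g("K", "E_rev"),
            g("T", "g_max"), g("T", "E_rev"),
            raw["I_bias"]["healthy" if condition == "healthy" else "pd"],
            _kin(raw, "m")["inf"]["theta"], _kin(raw, "m")["inf"]["k"],
            h["inf"]["theta"], h["inf"]["k"],
            h["tau"]["a0"], h["tau"]["a_theta"], h["tau"]["a_k"],
            h["tau"]["b0"], h["tau"]["b_theta"], h["tau"]["b_k"], h["phi"],
            _kin(raw, "p")["inf"]["theta"], _kin(raw, "p")["inf"]["k"],
            r["inf"]["theta"], r["inf"]["k"],
            r["tau"]["tau0"], r["tau"]["tau1"], r["tau"]["theta"], r["tau"]["k"],
            r["phi"],
        ],
        dtype=np.float64,
    )


def _pack_sigmoid_gate(kin):
    return [
        kin["inf"]["theta"], kin["inf"]["k"],
        kin["tau"]["tau0"], kin["tau"]["tau1"],
        kin["tau"]["theta"], kin["tau"]["k"], kin["phi"],
    ]


def pack_stn(raw: dict, condition: str) -> np.ndarray:
    g = lambda ch, k: _g(raw, ch, k)
    vals = [
        raw["C_m"], g("L", "g_max"), g("L", "E_rev"),
        g("Na", "g_max"), g("Na", "E_rev"), g("K", "g_max"), g("K", "E_rev"),
        g("Ca", "g_max"), g("Ca", "E_rev"), g("T", "g_max"), g("T", "E_rev"),
        raw["I_bias"]["healthy" if condition == "healthy" else "pd"],
        _kin(raw, "m")["inf"]["theta"], _kin(raw, "m")["inf"]["k"],
    ]
    vals += _pack_sigmoid_gate(_kin(raw, "h"))
    vals += _pack_sigmoid_gate(_kin(raw, "n"))
    vals += [
        _kin(raw, "s")["inf"]["theta"], _kin(raw, "s")["inf"]["k"],
        _kin(raw, "a")["inf"]["theta"], _kin(raw, "a")["inf"]["k"],
    ]
    vals += _pack_sigmoid_gate(_kin(raw, "r"))
    return np.array(vals, dtype=np.float64)


def pack_gp(raw: dict, condition: str) -> np.ndarray:
    g = lambda ch, k: _g(raw, ch, k)
    vals = [
        raw["C_m"], g("L", "g_max"), g("L", "E_rev"),
        g("Na", "g_max"), g("Na", "E_rev"), g("K", "g_max"), g("K", "E_rev"),
        g("Ca", "g_max"), g("Ca", "E_rev"), g("T", "g_max"), g("T", "E_rev"),
        raw["I_bias"]["healthy" if condition == "healthy" else "pd"],
        _kin(raw, "m")["inf"]["theta"], _kin(raw, "m")["inf"]["k"],
    ]
    vals += _pack_sigmoid_gate(_kin(raw, "h"))
    vals += _pack_sigmoid_gate(_kin(raw, "n"))
    vals += [
        _kin(raw, "a")["inf"]["theta"], _kin(raw, "a")["inf"]["k"],
        _kin(raw, "s")["inf"]["theta"], _kin(raw, "s")["inf"]["k"],
        _kin(raw, "r")["inf"]["theta"], _kin(raw, "r")["inf"]["k"],
        _kin(raw, "r")["tau"]["tau0"], _kin(raw, "r")["phi"],
    ]
    return np.array(vals, dtype=np.float64)


def pack_syn_kinetics(kin) -> np.ndarray:
    return np.array([kin.alpha, kin.beta, kin.theta, kin.k], dtype=np.float64)


# ---------------------------------------------------------------------------
# scalar right-hand sides


@njit(cache=True, fastmath=True, inline="always")
def _sig(V, theta, k):
    return 1.0 / (1.0 + math.exp(-(V - theta) / k))


@njit(cache=True, fastmath=True)
def th_rhs(V, h, r, I_syn, I_ext, p):
    m = _sig(V, p[10], p[11])
    IL = p[1] * (V - p[2])
    INa = p[3] * m * m * m * h * (V - p[4])
    nk = 0.75 * (1.0 - h)
    IK = p[5] * nk * nk * nk * nk * (V - p[6])
    pinf = _sig(V, p[21], p[22])
    IT = p[7] * pinf * pinf * r * (V - p[8])
    dV = (-IL - INa - IK - IT + I_syn + I_ext + p[9]) / p[0]
    hinf = _sig(V, p[12], p[13])
    a = p[14] * math.exp(-(V - p[15]) / p[16])
    b = p[17] / (1.0 + math.exp(-(V - p[18]) / p[19]))
    dh = p[20] * (hinf - h) * (a + b)
    rinf = _sig(V, p[23], p[24])
    taur = p[25] + p[26] * math.exp(-(V - p[27]) / p[28])
    dr = p[29] * (rinf - r) / taur
    return dV, dh, dr


@njit(cache=True, fastmath=True)
def stn_rhs(V, h, n, r, I_syn, I_ext, p):
    m = _sig(V, p[12], p[13])
    IL = p[1] * (V - p[2])
    INa = p[3] * m * m * m * h * (V - p[4])
    IK = p[5] * n * n * n * n * (V - p[6])
    s = _sig(V, p[28], p[29])
    ICa = p[7] * s * s * (V - p[8])
    a = _sig(V, p[30], p[31])
    b = 1.0 / (1.0 + math.exp((r - 0.4) / -0.1)) - 1.0 / (1.0 + math.exp(4.0))
    IT = p[9] * a * a * a * b * b * (V - p[10])
    dV = (-IL - INa - IK - ICa - IT + I_syn + I_ext + p[11]) / p[0]
    dh = p[20] * (_sig(V, p[14], p[15]) - h) / (
        p[16] + p[17] / (1.0 + math.exp(-(V - p[18]) / p[19]))
    )
    dn = p[27] * (_sig(V, p[21], p[22]) - n) / (
        p[23] + p[24] / (1.0 + math.exp(-(V - p[25]) / p[26]))
    )
    dr = p[38] * (_sig(V, p[32], p[33]) - r) / (
        p[34] + p[35] / (1.0 + math.exp(-(V - p[36]) / p[37]))
    )
    return dV, dh, dn, dr


@njit(cache=True, fastmath=True)
def gp_rhs(V, h, n, r, I_syn, I_ext, p):
    m = _sig(V, p[12], p[13])
    IL = p[1] * (V - p[2])
    INa = p[3] * m * m * m * h * (V - p[4])
    IK = p[5] * n * n * n * n * (V - p[6])
    s = _sig(V, p[30], p[31])
    ICa = p[7] * s * s * (V - p[8])
    a = _sig(V, p[28], p[29])
    IT = p[9] * a * a * a * r * (V - p[10])
    dV = (-IL - INa - IK - ICa - IT + I_syn + I_ext + p[11]) / p[0]
    dh = p[20] * (_sig(V, p[14], p[15]) - h) / (
        p[16] + p[17] / (1.0 + math.exp(-(V - p[18]) / p[19]))
    )
    dn = p[27] * (_sig(V, p[21], p[22]) - n) / (
        p[23] + p[24] / (1.0 + math.exp(-(V - p[25]) / p[26]))
    )
    dr = p[35] * (_sig(V, p[32], p[33]) - r) / p[34]
    return dV, dh, dn, dr


@njit(cache=True, fastmath=True)
def syn_gate_rhs(s, V_pre, kin):
    T = _sig(V_pre, kin[2], kin[3])
    return kin[0] * T * (1.0 - s) - kin[1] * s


# ---------------------------------------------------------------------------
# full-network derivative


@njit(cache=True, fastmath=True)
def network_deriv(
    Y, dY,
    i_smc, i_dbs_stn, i_dbs_gpe, i_dbs_gpi,
    th_p, stn_p, gpe_p, gpi_p,
    syn_g, syn_E, kin_exc, kin_inh,
    idx_gpi_th, idx_gpe_stn, idx_stn_gpe, idx_gpe_gpe, idx_stn_gpi, idx_gpe_gpi,
):
    n = Y.shape[1]
    for i in range(n):
        dY[15, i] = syn_gate_rhs(Y[15, i], Y[3, i], kin_exc)
        dY[16, i] = syn_gate_rhs(Y[16, i], Y[7, i], kin_inh)
        dY[17, i] = syn_gate_rhs(Y[17, i], Y[11, i], kin_inh)
    for i in range(n):
        # thalamus: 1 GPi afferent + SMC drive
        V = Y[0, i]
        s_sum = Y[17, idx_gpi_th[i, 0]]
        I_syn = -syn_g[0] * s_sum * (V - syn_E[0])
        dV, dh, dr = th_rhs(V, Y[1, i], Y[2, i], I_syn, i_smc, th_p)
        dY[0, i] = dV
        dY[1, i] = dh
        dY[2, i] = dr
    for i in range(n):
        # STN: 2 GPe afferents + DBS + bias
        V = Y[3, i]
        s_sum = Y[16, idx_gpe_stn[i, 0]] + Y[16, idx_gpe_stn[i, 1]]
        I_syn = -syn_g[1] * s_sum * (V - syn_E[1])
        dV, dh, dn, dr = stn_rhs(V, Y[4, i], Y[5, i], Y[6, i], I_syn, i_dbs_stn, stn_p)
        dY[3, i] = dV
        dY[4, i] = dh
        dY[5, i] = dn
        dY[6, i] = dr
    for i in range(n):
        # GPe: 2 STN + 2 GPe afferents + DBS + bias
        V = Y[7, i]
        se = Y[15, idx_stn_gpe[i, 0]] + Y[15, idx_stn_gpe[i, 1]]
        si = Y[16, idx_gpe_gpe[i, 0]] + Y[16, idx_gpe_gpe[i, 1]]
        I_syn = -syn_g[2] * se * (V - syn_E[2]) - syn_g[3] * si * (V - syn_E[3])
        dV, dh, dn, dr = gp_rhs(V, Y[8, i], Y[9, i], Y[10, i], I_syn, i_dbs_gpe, gpe_p)
        dY[7, i] = dV
        dY[8, i] = dh
        dY[9, i] = dn
        dY[10, i] = dr
    for i in range(n):
        # GPi: 2 STN + 2 GPe afferents + DBS + bias
        V = Y[11, i]
        se = Y[15, idx_stn_gpi[i, 0]] + Y[15, idx_stn_gpi[i, 1]]
        si = Y[16, idx_gpe_gpi[i, 0]] + Y[16, idx_gpe_gpi[i, 1]]
        I_syn = -syn_g[4] * se * (V - syn_E[4]) - syn_g[5] * si * (V - syn_E[5])
        dV, dh, dn, dr = gp_rhs(V, Y[12, i], Y[13, i], Y[14, i], I_syn, i_dbs_gpi, gpi_p)
        dY[11, i] = dV
        dY[12, i] = dh
        dY[13, i] = dn
        dY[14, i] = dr


@njit(cache=True, fastmath=True)
def run_network(
    Y, dt, n_steps, use_rk4,
    th_p, stn_p, gpe_p, gpi_p,
    syn_g, syn_E, kin_exc, kin_inh,
    idx_gpi_th, idx_gpe_stn, idx_stn_gpe, idx_gpe_gpe, idx_stn_gpi, idx_gpe_gpi,
    smc, dbs, dbs_stn, dbs_gpe, dbs_gpi,
    threshold, refractory,
    spike_times, spike_counts,
    rec_stride, traces,
):
    """Advance the packed state Y in place over n_steps.

    ``smc``/``dbs`` are per-step current samples (uA/cm^2); the dbs_* flags
    select the targeted populations.  Spikes (upward threshold crossings with
    a refractory window) are written to ``spike_times``/``spike_counts``
    (shape (4, n, max) / (4, n)).  If rec_stride > 0, the first
    ``traces.shape[1]`` voltages of each population are recorded every
    rec_stride steps.  Returns (status, t_ms, pop, neuron, clamp_events):
    status 1 flags numerical blow-up (|V| > 200 mV).
    """
    n = Y.shape[1]
    k1 = np.empty((NVAR, n))
    k2 = np.empty((NVAR, n))
    k3 = np.empty((NVAR, n))
    k4 = np.empty((NVAR, n))
    Yt = np.empty((NVAR, n))
    v_prev = np.empty((4, n))
    last_spike = np.full((4, n), -1.0e9)
    clamp_events = 0
    n_rec = traces.shape[1]
    max_spk = spike_times.shape[2]
    for it in range(n_steps):
        i_smc = smc[it]
        i_dbs = dbs[it]
        d_stn = i_dbs if dbs_stn else 0.0
        d_gpe = i_dbs if dbs_gpe else 0.0
        d_gpi = i_dbs if dbs_gpi else 0.0
        for q in range(4):
            vr = V_ROWS[q]
            for i in range(n):
                v_prev[q, i] = Y[vr, i]
        network_deriv(Y, k1, i_smc, d_stn, d_gpe, d_gpi,
                      th_p, stn_p, gpe_p, gpi_p, syn_g, syn_E, kin_exc, kin_inh,
                      idx_gpi_th, idx_gpe_stn, idx_stn_gpe, idx_gpe_gpe,
                      idx_stn_gpi, idx_gpe_gpi)
        if use_rk4:
            for v in range(NVAR):
                for i in range(n):
                    Yt[v, i] = Y[v, i] + 0.5 * dt * k1[v, i]
            network_deriv(Yt, k2, i_smc, d_stn, d_gpe, d_gpi,
                          th_p, stn_p, gpe_p, gpi_p, syn_g, syn_E, kin_exc, kin_inh,
                          idx_gpi_th, idx_gpe_stn, idx_stn_gpe, idx_gpe_gpe,
                          idx_stn_gpi, idx_gpe_gpi)
            for v in range(NVAR):
                for i in range(n):
                    Yt[v, i] = Y[v, i] + 0.5 * dt * k2[v, i]
            network_deriv(Yt, k3, i_smc, d_stn, d_gpe, d_gpi,
                          th_p, stn_p, gpe_p, gpi_p, syn_g, syn_E, kin_exc, kin_inh,
                          idx_gpi_th, idx_gpe_stn, idx_stn_gpe, idx_gpe_gpe,
                          idx_stn_gpi, idx_gpe_gpi)
            for v in range(NVAR):
                for i in range(n):
                    Yt[v, i] = Y[v, i] + dt * k3[v, i]
            network_deriv(Yt, k4, i_smc, d_stn, d_gpe, d_gpi,
                          th_p, stn_p, gpe_p, gpi_p, syn_g, syn_E, kin_exc, kin_inh,
                          idx_gpi_th, idx_gpe_stn, idx_stn_gpe, idx_gpe_gpe,
                          idx_stn_gpi, idx_gpe_gpi)
            c = dt / 6.0
            for v in range(NVAR):
                for i in range(n):
                    Y[v, i] += c * (
                        k1[v, i] + 2.0 * k2[v, i] + 2.0 * k3[v, i] + k4[v, i]
                    )
        else:
            for v in range(NVAR):
                for i in range(n):
                    Y[v, i] += dt * k1[v, i]
        # clamp gating variables into [0, 1]
        for gr in GATE_ROWS:
            for i in range(n):
                x = Y[gr, i]
                if x < 0.0:
                    if x < -1e-6:
                        clamp_events += 1
                    Y[gr, i] = 0.0
                elif x > 1.0:
                    if x > 1.0 + 1e-6:
                        clamp_events += 1
                    Y[gr, i] = 1.0
        t_now = (it + 1) * dt
        for q in range(4):
            vr = V_ROWS[q]
            for i in range(n):
                v_new = Y[vr, i]
                if abs(v_new) > 200.0:
                    return 1, t_now, q, i, clamp_events
                if (
                    v_prev[q, i] < threshold
                    and v_new > threshold
                    and t_now - last_spike[q, i] >= refractory
                ):
                    cnt = spike_counts[q, i]
                    if cnt < max_spk:
                        spike_times[q, i, cnt] = t_now
                        spike_counts[q, i] = cnt + 1
                    last_spike[q, i] = t_now
        if rec_stride > 0 and (it + 1) % rec_stride == 0:
            j = (it + 1) // rec_stride - 1
            if j < traces.shape[2]:
                for q in range(4):
                    vr = V_ROWS[q]
                    for i in range(n_rec):
                        traces[q, i, j] = Y[vr, i]
    return 0, n_steps * dt, -1, -1, clamp_events


@njit(cache=True, fastmath=True)
def run_single_stn(
    y, dt, n_steps, use_rk4, stn_p, i_ext, threshold, refractory,
    spike_times, trace,
):
    """Integrate one isolated STN neuron driven by the sampled current i_ext.

    ``y`` = [V, h, n, r] is advanced in place; returns the spike count.
    ``trace`` (len n_steps) receives V after each step if non-empty.
    """
    last_spike = -1.0e9
    count = 0
    max_spk = spike_times.shape[0]
    record = trace.shape[0] > 0
    V, h, n, r = y[0], y[1], y[2], y[3]
    for it in range(n_steps):
        ie = i_ext[it]
        v_prev = V
        dV1, dh1, dn1, dr1 = stn_rhs(V, h, n, r, 0.0, ie, stn_p)
        if use_rk4:
            dV2, dh2, dn2, dr2 = stn_rhs(
                V + 0.5 * dt * dV1, h + 0.5 * dt * dh1,
                n + 0.5 * dt * dn1, r + 0.5 * dt * dr1, 0.0, ie, stn_p)
            dV3, dh3, dn3, dr3 = stn_rhs(
                V + 0.5 * dt * dV2, h + 0.5 * dt * dh2,
                n + 0.5 * dt * dn2, r + 0.5 * dt * dr2, 0.0, ie, stn_p)
            dV4, dh4, dn4, dr4 = stn_rhs(
                V + dt * dV3, h + dt * dh3, n + dt * dn3, r + dt * dr3,
                0.0, ie, stn_p)
            V += dt / 6.0 * (dV1 + 2.0 * dV2 + 2.0 * dV3 + dV4)
            h += dt / 6.0 * (dh1 + 2.0 * dh2 + 2.0 * dh3 + dh4)
            n += dt / 6.0 * (dn1 + 2.0 * dn2 + 2.0 * dn3 + dn4)
            r += dt / 6.0 * (dr1 + 2.0 * dr2 + 2.0 * dr3 + dr4)
        else:
            V += dt * dV1
            h += dt * dh1
            n += dt * dn1
            r += dt * dr1
        h = min(max(h, 0.0), 1.0)
        n = min(max(n, 0.0), 1.0)
        r = min(max(r, 0.0), 1.0)
        t_now = (it + 1) * dt
        if v_prev < threshold and V > threshold and t_now - last_spike >= refractory:
            if count < max_spk:
                spike_times[count] = t_now
            count += 1
            last_spike = t_now
        if record:
            trace[it] = V
    y[0], y[1], y[2], y[3] = V, h, n, r
    return count
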