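"""Conductance-scalable iPSC-CM ionic model (Kernik et al. 2019 formulation).

The model describes a spontaneously beating human induced pluripotent stem
cell-derived cardiomyocyte: 13 membrane currents, a Shannon-type sarcoplasmic
reticulum (RyR release, SERCA uptake, passive leak) and ten Tusscher-style
intracellular buffering.  Every maximal conductance / flux amplitude is
scaled by a dimensionless multiplier so that populations of cells and
channel-block experiments are expressed as multiplier vectors
(see :mod:`cmcal.types`).

Two integration back-ends share the same right-hand side:

* ``adaptive`` — a numba-compiled hybrid scheme: exact exponential
  (Rush-Larsen) updates for the 14 Hodgkin-Huxley gates, forward Euler for
  membrane potential, concentrations and RyR states, with the step size
  adapted to dV/dt and calcium flux rates.  This is the workhorse for
  population simulations and genetic-algorithm calibration.
* ``lsoda`` — SciPy's stiff/non-stiff switching solver on the full system,
  used as the accuracy reference.

State layout (index, name, unit)::

    0 V (mV)      1 Ca_SR (mM)  2 Cai (mM)   3 Nai (mM)  4 Ki (mM)
    5 m  6 h  7 j             I_Na gates
    8 d  9 f  10 fCa          I_CaL gates
    11 Xr1  12 Xr2            I_Kr gates
    13 Xs                     I_Ks gate
    14 Xf                     I_f gate
    15 r  16 s                I_to gates
    17 dCaT  18 fCaT          I_CaT gates
    19 R  20 O  21 I          RyR (Shannon) states
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Physical constants and cell geometry
# ---------------------------------------------------------------------------
F = 96.4853415          # C/mmol
RGAS = 8.314472         # J/(mol K)
T = 310.0               # K
RTF = RGAS * T / F      # mV

CM = 60.0               # pF, membrane capacitance
V_TOT = 3960.0          # um^3, total cell volume
_VC_TENT = 16404.0
_VSR_TENT = 1094.0
VC = V_TOT * _VC_TENT / (_VC_TENT + _VSR_TENT)    # cytosolic volume
VSR = V_TOT * _VSR_TENT / (_VC_TENT + _VSR_TENT)  # SR volume

N_STATES = 22
N_GATES = 17      # 14 HH gates + 3 RyR states, all updated exponentially
GATE_OFFSET = 5   # gates occupy states 5..21

STATE_NAMES: tuple[str, ...] = (
    "V", "Ca_SR", "Cai", "Nai", "Ki",
    "m", "h", "j", "d", "f", "fCa", "Xr1", "Xr2", "Xs", "Xf",
    "r", "s", "dCaT", "fCaT", "RyR_R", "RyR_O", "RyR_I",
)

# ---------------------------------------------------------------------------
# Baseline maximal conductances / flux amplitudes (multiplier = 1)
# Order matches cmcal.types.CONDUCTANCE_NAMES.
# ---------------------------------------------------------------------------
G_NA = 9.720613409241       # nS/pF
G_F = 0.0435                # nS/pF
P_CAL = 0.308027691379846   # nS/pF (Shannon-style permeability scale)
G_CAT = 0.0925              # nS/pF
G_TO = 0.117833333333333    # nS/pF
G_KR = 0.218025             # nS/pF
G_KS = 0.0077               # nS/pF
G_K1 = 0.200678666696409    # nS/pF
P_NAK = 2.4761              # pA/pF
K_NACA = 1100.0             # pA/pF
G_PCA = 0.2625              # pA/pF
G_B_NA = 0.000435           # nS/pF
G_B_CA = 0.000367           # nS/pF
V_MAX_UP = 0.0002125        # mM/ms (SERCA)
V_LEAK = 1.6e-6             # 1/ms   (SR leak rate constant)
KS_REL = 12.5               # 1/ms   (RyR release rate constant)
KO_CA = 56320.0             # mM^-2 ms^-1 (RyR opening)
KI_CA = 108.0               # mM^-1 ms^-1 (RyR inactivation)
K_OM = 1.5                  # 1/ms (RyR closing)
K_IM = 0.4                  # 1/ms (RyR recovery)
BUF_C = 0.15                # mM (cytosolic Ca buffer)
KBUF_C = 0.001              # mM
BUF_SR = 12.0               # mM (SR Ca buffer)
KBUF_SR = 0.3               # mM


@njit(cache=True)
def _derivs(y, g, nao, cao, ko, istim, dy, ginf, gtau, cur):
    """Full right-hand side.

    Fills ``dy`` (22), ``ginf``/``gtau`` (14, gate steady states and time
    constants for Rush-Larsen updates) and ``cur`` (16 instrumented currents
    and fluxes, ordered as cmcal.types.CURRENT_NAMES).
    ``istim`` is the signed stimulus current density (pA/pF, inward < 0).
    """
    V = y[0]
    ca_sr = y[1]
    cai = y[2]
    nai = y[3]
    ki = y[4]
    m = y[5]; h = y[6]; jj = y[7]
    d = y[8]; f = y[9]; fca = y[10]
    xr1 = y[11]; xr2 = y[12]
    xs = y[13]
    xf = y[14]
    r = y[15]; s = y[16]
    d_cat = y[17]; f_cat = y[18]
    ry_r = y[19]; ry_o = y[20]; ry_i = y[21]

    if cai < 1e-9:
        cai = 1e-9
    if ca_sr < 1e-9:
        ca_sr = 1e-9

    e_k = RTF * np.log(ko / ki)
    e_na = RTF * np.log(nao / nai)
    e_ca = 0.5 * RTF * np.log(cao / cai)

    # --- I_Na (m^3 h j) --------------------------------------------------
    m1 = 108.045846384818; m2 = 13.107015733941
    m5 = 0.002326914367; m6 = -7.917726289513
    m3 = m5 * m1; m4 = 1.0 / (1.0 / m2 + 1.0 / m6)
    h1 = 0.003626598864; h2 = -19.839358860026
    h5 = 9663.29497711474; h6 = 7.395503564613
    h3 = h5 * h1; h4 = 1.0 / (1.0 / h2 + 1.0 / h6)
    j1 = 0.000512257182000000; j2 = -66.583755502652
    j5 = h5; j6 = h6
    j3 = j5 * j1; j4 = 1.0 / (1.0 / j2 + 1.0 / j6)

    a_m = m1 * np.exp(V / m2); b_m = m3 * np.exp(V / m4)
    a_h = h1 * np.exp(V / h2); b_h = h3 * np.exp(V / h4)
    a_j = j1 * np.exp(V / j2); b_j = j3 * np.exp(V / j4)
    ginf[0] = a_m / (a_m + b_m); gtau[0] = 1.0 / (a_m + b_m) + 0.031977580384
    ginf[1] = a_h / (a_h + b_h); gtau[1] = 1.0 / (a_h + b_h) + 0.167331502516
    ginf[2] = a_j / (a_j + b_j); gtau[2] = 1.0 / (a_j + b_j) + 0.951088724962

    i_na = g[0] * G_NA * m * m * m * h * jj * (V - e_na)

    # --- I_f (funny current, mixed Na/K) ---------------------------------
    xf1 = 5.7897e-7; xf2 = -14.5897121702
    xf5 = 20086.6502378844; xf6 = 10.20235284528
    xf3 = xf5 * xf1; xf4 = 1.0 / (1.0 / xf2 + 1.0 / xf6)
    a_xf = xf1 * np.exp(V / xf2); b_xf = xf3 * np.exp(V / xf4)
    ginf[9] = a_xf / (a_xf + b_xf)
    gtau[9] = 1.0 / (a_xf + b_xf) + 43.8498855338097
    na_frac = 0.491 / (1.0 + 0.491)
    gf = g[1] * G_F * xf
    i_f_na = na_frac * gf * (V - e_na)
    i_f_k = (1.0 - na_frac) * gf * (V - e_k)
    i_f = i_f_na + i_f_k

    # --- I_CaL (GHK-like driving terms, Shannon permeability split) ------
    d1 = 12.9661194976997; d2 = 7.07914596471100
    d5 = 0.044909416; d6 = -6.90988036924199
    d3 = d5 * d1; d4 = 1.0 / (1.0 / d2 + 1.0 / d6)
    f1 = 0.000512589825763190; f2 = -49.5057120965066
    f5 = 1931.21122351432; f6 = 5.73002756270754
    f3 = f5 * f1; f4 = 1.0 / (1.0 / f2 + 1.0 / f6)
    a_d = d1 * np.exp(V / d2); b_d = d3 * np.exp(V / d4)
    a_f = f1 * np.exp(V / f2); b_f = f3 * np.exp(V / f4)
    ginf[3] = a_d / (a_d + b_d); gtau[3] = 1.0 / (a_d + b_d) + 1.65824694683
    ginf[4] = a_f / (a_f + b_f); gtau[4] = 1.0 / (a_f + b_f) + 100.462559171103

    # Ca-dependent inactivation gate
    sc = 1.2
    a_fca = 1.0 / (1.0 + (sc * cai / 0.000325) ** 8)
    b_fca = 0.1 / (1.0 + np.exp((sc * cai - 0.0005) / 0.0001))
    g_fca = 0.2 / (1.0 + np.exp((sc * cai - 0.00075) / 0.0008))
    fca_inf = (a_fca + b_fca + g_fca + 0.23) / 1.46
    if fca_inf > fca and V > -60.0:
        # inactivation may not relax during depolarization
        ginf[5] = fca
    else:
        ginf[5] = fca_inf
    gtau[5] = 2.0

    p_ca_sh = 5.4e-4; p_na_sh = 1.5e-8; p_k_sh = 2.7e-7
    p_tot = p_ca_sh + p_na_sh + p_k_sh
    p_cal = g[2] * P_CAL
    vfrt = V * F / (RGAS * T)
    vv = V
    if -1e-6 < vv < 1e-6:       # remove the removable singularity at V = 0
        vv = 1e-6
        vfrt = vv * F / (RGAS * T)
    ex2 = np.exp(2.0 * vfrt)
    ex1 = np.exp(vfrt)
    ibar_ca = (p_cal * p_ca_sh / p_tot) * 4.0 * vv * F / RTF * \
        (0.341 * cai * ex2 - 0.341 * cao) / (ex2 - 1.0)
    ibar_na = (p_cal * p_na_sh / p_tot) * vv * F / RTF * \
        (0.75 * nai * ex1 - 0.75 * nao) / (ex1 - 1.0)
    ibar_k = (p_cal * p_k_sh / p_tot) * vv * F / RTF * \
        (0.75 * ki * ex1 - 0.75 * ko) / (ex1 - 1.0)
    gate_cal = d * f * fca
    i_cal_ca = ibar_ca * gate_cal
    i_cal_na = ibar_na * gate_cal
    i_cal_k = ibar_k * gate_cal
    i_cal = i_cal_ca + i_cal_na + i_cal_k

    # --- I_CaT (T-type calcium) ------------------------------------------
    ginf[12] = 1.0 / (1.0 + np.exp(-(V + 26.3) / 6.0))
    gtau[12] = 1.0 / (1.068 * np.exp((V + 26.3) / 30.0)
                      + 1.068 * np.exp(-(V + 26.3) / 30.0))
    ginf[13] = 1.0 / (1.0 + np.exp((V + 61.7) / 5.6))
    gtau[13] = 1.0 / (0.0153 * np.exp(-(V + 61.7) / 83.3)
                      + 0.015 * np.exp((V + 61.7) / 15.38))
    i_cat = g[3] * G_CAT * d_cat * f_cat * (V - e_ca)

    # --- I_to (transient outward K) --------------------------------------
    r1 = 0.0553614181713; r2 = 11.6842023429669
    r5 = 3.98918108037750; r6 = -11.0471393012032
    r3 = r5 * r1; r4 = 1.0 / (1.0 / r2 + 1.0 / r6)
    s1 = 0.000344230464735980; s2 = -17.6344722898096
    s5 = 186.760536547014; s6 = 8.18093387332270
    s3 = s5 * s1; s4 = 1.0 / (1.0 / s2 + 1.0 / s6)
    a_r = r1 * np.exp(V / r2); b_r = r3 * np.exp(V / r4)
    a_s = s1 * np.exp(V / s2); b_s = s3 * np.exp(V / s4)
    ginf[10] = a_r / (a_r + b_r); gtau[10] = 1.0 / (a_r + b_r) + 0.696758421171499
    ginf[11] = a_s / (a_s + b_s); gtau[11] = 1.0 / (a_s + b_s) + 11.2244577239469
    i_to = g[4] * G_TO * r * s * (V - e_k)

    # --- I_Kr (rapid delayed rectifier) ----------------------------------
    q1 = 0.00574885237435; q2 = 13.6234926362576
    q5 = 0.047630571181836; q6 = -7.06808742965549
    q3 = q5 * q1; q4 = 1.0 / (1.0 / q2 + 1.0 / q6)
    w1 = 0.012456640526827; w2 = -25.9944581644377
    w5 = 37.3263331116086; w6 = 22.091964153303
    w3 = w5 * w1; w4 = 1.0 / (1.0 / w2 + 1.0 / w6)
    a_x1 = q1 * np.exp(V / q2); b_x1 = q3 * np.exp(V / q4)
    a_x2 = w1 * np.exp(V / w2); b_x2 = w3 * np.exp(V / w4)
    ginf[6] = a_x1 / (a_x1 + b_x1); gtau[6] = 1.0 / (a_x1 + b_x1) + 50.0
    ginf[7] = a_x2 / (a_x2 + b_x2); gtau[7] = 1.0 / (a_x2 + b_x2)
    i_kr = g[5] * G_KR * np.sqrt(ko / 5.4) * xr1 * xr2 * (V - e_k)

    # --- I_Ks (slow delayed rectifier) -----------------------------------
    y1 = 0.001166353759153; y2 = 66.726447608045
    y5 = 0.280458908250097; y6 = -18.866972150622
    y3 = y5 * y1; y4 = 1.0 / (1.0 / y2 + 1.0 / y6)
    a_xs = y1 * np.exp(V / y2); b_xs = y3 * np.exp(V / y4)
    ginf[8] = a_xs / (a_xs + b_xs); gtau[8] = 1.0 / (a_xs + b_xs)
    i_ks = g[6] * G_KS * xs * xs * (V - e_k)

    # --- I_K1 (inward rectifier, instantaneous) --------------------------
    a_k1 = 0.477994972217041 * np.exp((V + 4.925023318814251) / 27.242756176907)
    b_k1 = np.exp((V + 56.6361974777629) / 8.7222376098864)
    xk1_inf = a_k1 / (a_k1 + b_k1)
    i_k1 = g[7] * G_K1 * np.sqrt(ko / 5.4) * xk1_inf * (V - e_k)

    # --- pumps and exchangers --------------------------------------------
    km_k = 1.0; km_na = 40.0
    i_nak = g[8] * P_NAK * ko * nai / (
        (ko + km_k) * (nai + km_na)
        * (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt)))

    km_ca = 1.38; km_nai = 87.5; ksat = 0.1; gam = 0.35; alp = 2.5
    i_naca = g[9] * K_NACA * (
        np.exp(gam * vfrt) * nai ** 3 * cao
        - np.exp((gam - 1.0) * vfrt) * nao ** 3 * cai * alp) / (
        (km_nai ** 3 + nao ** 3) * (km_ca + cao)
        * (1.0 + ksat * np.exp((gam - 1.0) * vfrt)))

    i_pca = g[10] * G_PCA * cai / (cai + 0.0005)
    i_b_na = g[11] * G_B_NA * (V - e_na)
    i_b_ca = g[12] * G_B_CA * (V - e_ca)

    # --- SR fluxes (cytosolic mM/ms) -------------------------------------
    kup = 0.00025
    j_up = g[13] * V_MAX_UP / (1.0 + (kup / cai) ** 2)
    j_leak = g[14] * V_LEAK * (ca_sr - cai)

    max_sr = 15.0; min_sr = 1.0; ec50_sr = 0.45
    k_casr = max_sr - (max_sr - min_sr) / (1.0 + (ec50_sr / ca_sr) ** 2.5)
    ko_srca = KO_CA / k_casr       # mM^-2 ms^-1 (operates on bulk Cai)
    ki_srca = KI_CA * k_casr       # mM^-1 ms^-1
    kom = K_OM; kim = K_IM
    ry_ri = 1.0 - ry_r - ry_o - ry_i
    ko2 = ko_srca * cai * cai
    ki1 = ki_srca * cai
    # each RyR state is linear given the others: dX = A - B*X, exported as
    # inf = A/B, tau = 1/B so the integrator can update it exponentially
    b_r = kim + ki1 + ko2
    a_r = kim * (1.0 - ry_o - ry_i) + kom * ry_o
    b_o = kom + ki1
    a_o = ko2 * ry_r + kim * ry_i
    b_i = kim + kom + ko2
    a_i = ki1 * ry_o + ko2 * (1.0 - ry_r - ry_o)
    ginf[14] = a_r / b_r; gtau[14] = 1.0 / b_r
    ginf[15] = a_o / b_o; gtau[15] = 1.0 / b_o
    ginf[16] = a_i / b_i; gtau[16] = 1.0 / b_i
    j_rel = g[15] * KS_REL * ry_o * (ca_sr - cai) * (VSR / VC)

    # --- balance equations ------------------------------------------------
    i_ion = (i_k1 + i_to + i_kr + i_ks + i_cal + i_cat + i_nak + i_na
             + i_naca + i_pca + i_f + i_b_na + i_b_ca)
    dy[0] = -(i_ion + istim)

    buf_sr = 1.0 / (1.0 + BUF_SR * KBUF_SR / (ca_sr + KBUF_SR) ** 2)
    buf_c = 1.0 / (1.0 + BUF_C * KBUF_C / (cai + KBUF_C) ** 2)
    dy[1] = buf_sr * (VC / VSR) * (j_up - j_leak - j_rel)
    dy[2] = buf_c * (j_leak - j_up + j_rel
                     - (i_cal_ca + i_cat + i_b_ca + i_pca - 2.0 * i_naca)
                     * CM / (2.0 * VC * F))
    dy[3] = -(i_na + i_b_na + i_f_na + i_cal_na + 3.0 * i_nak
              + 3.0 * i_naca) * CM / (VC * F)
    dy[4] = -(i_k1 + i_to + i_kr + i_ks + i_f_k + i_cal_k + istim
              - 2.0 * i_nak) * CM / (VC * F)

    for k in range(N_GATES):
        dy[GATE_OFFSET + k] = (ginf[k] - y[GATE_OFFSET + k]) / gtau[k]

    cur[0] = i_na; cur[1] = i_f; cur[2] = i_cal; cur[3] = i_cat
    cur[4] = i_to; cur[5] = i_kr; cur[6] = i_ks; cur[7] = i_k1
    cur[8] = i_nak; cur[9] = i_naca; cur[10] = i_pca
    cur[11] = i_b_na; cur[12] = i_b_ca
    cur[13] = j_up; cur[14] = j_leak; cur[15] = j_rel


@njit(cache=True)
def _stim_current(t, amp, width, period):
    """Signed stimulus density at time t; first pulse starts at t = period."""
    if period <= 0.0:
        return 0.0
    k = int(t / period)
    if k >= 1 and (t - k * period) < width:
        return -amp
    return 0.0


@njit(cache=True)
def _next_stim_edge(t, width, period):
    if period <= 0.0:
        return 1e30
    k = int(t / period)
    if k >= 1 and (t - k * period) < width:
        return k * period + width
    return (k + 1) * period


@njit(cache=True)
def _integrate(y, g, nao, cao, ko, amp, width, period,
               duration, dt_out, record_start, dt_max,
               out_v, out_ca):
    """Adaptive Rush-Larsen / Euler integration with dense output.

    Mutates ``y`` to the final state and fills ``out_v`` / ``out_ca`` on the
    grid ``record_start + i*dt_out``.  Returns 0 on success, 1 on failure
    (non-finite state or membrane potential outside [-150, 100] mV).
    """
    dy = np.empty(N_STATES)
    ginf = np.empty(N_GATES)
    gtau = np.empty(N_GATES)
    cur = np.empty(16)

    n_out = out_v.shape[0]
    i_out = 0
    t = 0.0
    eps = 1e-9
    dt_min = 5e-4
    # step budget: average dt below ~0.02 ms over the whole run means the
    # cell is in a pathological crawl; flag it instead of burning CPU
    max_steps = int(duration * 50.0) + 1000000
    n_steps = 0

    # sample at t = 0 if the grid starts there
    if n_out > 0 and record_start <= eps:
        out_v[0] = y[0]
        out_ca[0] = y[2]
        i_out = 1

    while t < duration - eps:
        n_steps += 1
        if n_steps > max_steps:
            return 2
        istim = _stim_current(t, amp, width, period)
        _derivs(y, g, nao, cao, ko, istim, dy, ginf, gtau, cur)

        dt = dt_max
        adv = abs(dy[0])
        if adv > 0.0:
            h1 = 0.25 / adv
            if h1 < dt:
                dt = h1
        adca = abs(dy[2])
        if adca > 0.0:
            h2 = (0.005 * y[2] + 2e-7) / adca
            if h2 < dt:
                dt = h2
        adsr = abs(dy[1])
        if adsr > 0.0:
            h3 = (0.005 * y[1] + 1e-5) / adsr
            if h3 < dt:
                dt = h3
        if dt < dt_min:
            dt = dt_min

        # never step across a stimulus edge, the end, or an output sample
        edge = _next_stim_edge(t, width, period)
        if edge - t < dt:
            dt = edge - t
        if duration - t < dt:
            dt = duration - t
        if i_out < n_out:
            t_next_out = record_start + i_out * dt_out
            if t_next_out > t + eps and t_next_out - t < dt:
                dt = t_next_out - t
        if dt < 1e-6:
            # clamping to an edge can produce a zero-length step that float
            # addition cannot represent; overstep by <1 us instead
            dt = 1e-6

        # advance: Euler for V, concentrations, RyR; Rush-Larsen for gates
        y[0] += dt * dy[0]
        y[1] += dt * dy[1]
        y[2] += dt * dy[2]
        y[3] += dt * dy[3]
        y[4] += dt * dy[4]
        for k in range(N_GATES):
            tk = gtau[k]
            if tk < 1e-10:
                y[GATE_OFFSET + k] = ginf[k]
            else:
                y[GATE_OFFSET + k] = ginf[k] + (y[GATE_OFFSET + k] - ginf[k]) \
                    * np.exp(-dt / tk)
        if y[1] < 1e-9:
            y[1] = 1e-9
        if y[2] < 1e-9:
            y[2] = 1e-9
        t += dt

        if not np.isfinite(y[0]) or y[0] < -150.0 or y[0] > 100.0:
            return 1
        if not (np.isfinite(y[2]) and np.isfinite(y[1]) and np.isfinite(y[3])):
            return 1

        while i_out < n_out and t >= record_start + i_out * dt_out - eps:
            out_v[i_out] = y[0]
            out_ca[i_out] = y[2]
            i_out += 1

    return 0


def rhs(t: float, y: np.ndarray, g: np.ndarray, nao: float, cao: float,
        ko: float, amp: float = 0.0, width: float = 0.0,
        period: float = 0.0) -> np.ndarray:
    """Plain-function right-hand side (for SciPy solvers and inspection)."""
    dy = np.empty(N_STATES)
    ginf = np.empty(N_GATES)
    gtau = np.empty(N_GATES)
    cur = np.empty(16)
    _derivs(np.asarray(y, dtype=float), g, nao, cao, ko,
            _stim_current(t, amp, width, period), dy, ginf, gtau, cur)
    return dy


def currents(y: np.ndarray, g: np.ndarray, nao: float, cao: float,
             ko: float) -> np.ndarray:
    """Instrumented membrane currents (pA/pF) and SR fluxes (mM/ms).

    Ordered as :data:`cmcal.types.CURRENT_NAMES`.
    """
    dy = np.empty(N_STATES)
    ginf = np.empty(N_GATES)
    gtau = np.empty(N_GATES)
    cur = np.empty(16)
    _derivs(np.asarray(y, dtype=float), np.asarray(g, dtype=float),
            nao, cao, ko, 0.0, dy, ginf, gtau, cur)
    return cur


def rest_state(v: float = -75.6) -> np.ndarray:
    """A physiologically sensible starting state (gates at steady state).

    This is only a seed for :func:`cmcal.simulate.derive_initial_state`,
    which relaxes the model onto its limit cycle.
    """
    y = np.zeros(N_STATES)
    y[0] = v
    y[1] = 0.33
    y[2] = 0.00022
    y[3] = 7.2
    y[4] = 104.7
    ginf = np.empty(N_GATES)
    gtau = np.empty(N_GATES)
    dy = np.empty(N_STATES)
    cur = np.empty(16)
    y[GATE_OFFSET:GATE_OFFSET + N_GATES] = 0.5
    _derivs(y, np.ones(16), 151.0, 1.8, 5.4, 0.0, dy, ginf, gtau, cur)
    y[GATE_OFFSET:GATE_OFFSET + N_GATES] = ginf
    y[19] = 0.99
    y[20] = 1e-4
    y[21] = 1e-4
    return y
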