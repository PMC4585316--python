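"""Numba kernels for the Luo-Rudy phase-I (LR1) membrane model.

Scalar rate functions are transcribed once here and reused by the table
builder and the single-cell integrator.  The strand solver
(:mod:`strandcv._propagate`) consumes the per-cell-type lookup tables built
by :func:`build_rl_tables`.

Units: V in mV, time in ms, currents in uA/cm2, conductances in mS/cm2,
[Ca]i in mmol/L.  Membrane capacitance is 1 uF/cm2 so dV/dt in mV/ms equals
the total current density in uA/cm2 with opposite sign.
"""

import math

import numpy as np
from numba import njit

# Fixed LR1 constants (standard concentrations, 37 C)
RTF = 26.73  # mV
E_NA = 54.4
K_O, K_I = 5.4, 145.0
E_K = -77.0  # time-dependent K+ current reversal (includes Na+ permeability)
E_K1 = RTF * math.log(K_O / K_I)  # ~ -87.9 mV; also used for the plateau K+ current
G_K1_BAR = 0.6047 * math.sqrt(K_O / 5.4)
G_K_BAR = 0.282 * math.sqrt(K_O / 5.4)
G_SI_BAR = 0.09
G_B = 0.03921
E_B = -59.87
CAI_REST = 1.0e-4


@njit(cache=True)
def _safe_exp(x):
    if x > 80.0:
        x = 80.0
    return math.exp(x)


@njit(cache=True)
def rates_m(v):
    dv = v + 47.13
    if abs(dv) < 1e-7:
        a = 3.2  # limit of 0.32*dv/(1-exp(-0.1*dv))
    else:
        a = 0.32 * dv / (1.0 - _safe_exp(-0.1 * dv))
    b = 0.08 * _safe_exp(-v / 11.0)
    return a, b


@njit(cache=True)
def rates_h(v):
    if v < -40.0:
        a = 0.135 * _safe_exp(-(80.0 + v) / 6.8)
        b = 3.56 * _safe_exp(0.079 * v) + 3.1e5 * _safe_exp(0.35 * v)
    else:
        a = 0.0
        b = 1.0 / (0.13 * (1.0 + _safe_exp(-(v + 10.66) / 11.1)))
    return a, b


@njit(cache=True)
def rates_j(v):
    if v < -40.0:
        a = (
            (-1.2714e5 * _safe_exp(0.2444 * v) - 3.474e-5 * _safe_exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + _safe_exp(0.311 * (v + 79.23)))
        )
        b = 0.1212 * _safe_exp(-0.01052 * v) / (1.0 + _safe_exp(-0.1378 * (v + 40.14)))
    else:
        a = 0.0
        b = 0.3 * _safe_exp(-2.535e-7 * v) / (1.0 + _safe_exp(-0.1 * (v + 32.0)))
    return a, b


@njit(cache=True)
def rates_d(v):
    a = 0.095 * _safe_exp(-0.01 * (v - 5.0)) / (1.0 + _safe_exp(-0.072 * (v - 5.0)))
    b = 0.07 * _safe_exp(-0.017 * (v + 44.0)) / (1.0 + _safe_exp(0.05 * (v + 44.0)))
    return a, b


@njit(cache=True)
def rates_f(v):
    a = 0.012 * _safe_exp(-0.008 * (v + 28.0)) / (1.0 + _safe_exp(0.15 * (v + 28.0)))
    b = 0.0065 * _safe_exp(-0.02 * (v + 30.0)) / (1.0 + _safe_exp(-0.2 * (v + 30.0)))
    return a, b


@njit(cache=True)
def rates_x(v):
    a = 0.0005 * _safe_exp(0.083 * (v + 50.0)) / (1.0 + _safe_exp(0.057 * (v + 50.0)))
    b = 0.0013 * _safe_exp(-0.06 * (v + 20.0)) / (1.0 + _safe_exp(-0.04 * (v + 20.0)))
    return a, b


@njit(cache=True)
def xi_factor(v):
    """Inward-rectification factor of the time-dependent K+ current."""
    if v <= -100.0:
        return 1.0
    dv = v + 77.0
    if abs(dv) < 1e-7:
        return 2.837 * 0.04 / _safe_exp(0.04 * (v + 35.0))
    return 2.837 * (_safe_exp(0.04 * dv) - 1.0) / (dv * _safe_exp(0.04 * (v + 35.0)))


@njit(cache=True)
def k1_inf(v):
    a = 1.02 / (1.0 + _safe_exp(0.2385 * (v - E_K1 - 59.215)))
    b = (
        0.49124 * _safe_exp(0.08032 * (v - E_K1 + 5.476))
        + _safe_exp(0.06175 * (v - E_K1 - 594.31))
    ) / (1.0 + _safe_exp(-0.5143 * (v - E_K1 + 4.753)))
    return a / (a + b)


@njit(cache=True)
def i_static(v):
    """Gate-free outward currents: I_K1 + I_Kp + I_b (uA/cm2)."""
    ik1 = G_K1_BAR * k1_inf(v) * (v - E_K1)
    kp = 1.0 / (1.0 + _safe_exp((7.488 - v) / 5.98))
    ikp = 0.0183 * kp * (v - E_K1)
    ib = G_B * (v - E_B)
    return ik1 + ikp + ib


@njit(cache=True)
def e_si(cai):
    return 7.7 - 13.0287 * math.log(cai)


@njit(cache=True)
def cell_derivatives(v, m, h, j, d, f, x, cai, gna, gsi_scale, tau_d_scale,
                     tau_f_scale, gk_scale, i_stim):
    """Full LR1 right-hand side for one cell; returns the 8 time-derivatives."""
    am, bm = rates_m(v)
    ah, bh = rates_h(v)
    aj, bj = rates_j(v)
    ad, bd = rates_d(v)
    af, bf = rates_f(v)
    ax, bx = rates_x(v)

    ina = gna * m * m * m * h * j * (v - E_NA)
    isi = G_SI_BAR * gsi_scale * d * f * (v - e_si(cai))
    ik = G_K_BAR * gk_scale * x * xi_factor(v) * (v - E_K)
    itot = ina + isi + ik + i_static(v)

    dv = -(itot - i_stim)  # Cm = 1 uF/cm2
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dj = aj * (1.0 - j) - bj * j
    dd = (ad * (1.0 - d) - bd * d) / tau_d_scale
    df = (af * (1.0 - f) - bf * f) / tau_f_scale
    dx = ax * (1.0 - x) - bx * x
    dcai = -1.0e-4 * isi + 0.07 * (CAI_REST - cai)
    return dv, dm, dh, dj, dd, df, dx, dcai


# ------------------------------------------------------------------
# Rush-Larsen lookup tables
# ------------------------------------------------------------------
# Column layout of a table row (at one voltage):
#  0 m_inf   1 exp(-dt/tau_m)
#  2 h_inf   3 exp(-dt/tau_h)
#  4 j_inf   5 exp(-dt/tau_j)
#  6 d_inf   7 exp(-dt/tau_d)   (tau scaled per cell type)
#  8 f_inf   9 exp(-dt/tau_f)   (tau scaled per cell type)
# 10 X_inf  11 exp(-dt/tau_X)
# 12 Xi(V)  13 I_K1+I_Kp+I_b
N_TABLE_COLS = 14
V_TABLE_MIN = -110.0
V_TABLE_MAX = 80.0
V_TABLE_STEP = 0.05


@njit(cache=True)
def _fill_table(table, dt, tau_d_scale, tau_f_scale):
    n = table.shape[0]
    for i in range(n):
        v = V_TABLE_MIN + i * V_TABLE_STEP
        am, bm = rates_m(v)
        ah, bh = rates_h(v)
        aj, bj = rates_j(v)
        ad, bd = rates_d(v)
        af, bf = rates_f(v)
        ax, bx = rates_x(v)
        table[i, 0] = am / (am + bm)
        table[i, 1] = math.exp(-dt * (am + bm))
        table[i, 2] = ah / (ah + bh)
        table[i, 3] = math.exp(-dt * (ah + bh))
        table[i, 4] = aj / (aj + bj)
        table[i, 5] = math.exp(-dt * (aj + bj))
        table[i, 6] = ad / (ad + bd)
        table[i, 7] = math.exp(-dt * (ad + bd) / tau_d_scale)
        table[i, 8] = af / (af + bf)
        table[i, 9] = math.exp(-dt * (af + bf) / tau_f_scale)
        table[i, 10] = ax / (ax + bx)
        table[i, 11] = math.exp(-dt * (ax + bx))
        table[i, 12] = xi_factor(v)
        table[i, 13] = i_static(v)


def build_rl_tables(dt, tau_d_scales, tau_f_scales):
    """Per-cell-type Rush-Larsen tables for time step ``dt``.

    Parameters
    ----------
    dt : float
        Integration step, ms.
    tau_d_scales, tau_f_scales : sequence of float
        One entry per cell type; multiply the Ca2+ gate time constants.

    Returns
    -------
    ndarray of shape (n_types, n_voltages, 14)
    """
    n_types = len(tau_d_scales)
    n_v = int(round((V_TABLE_MAX - V_TABLE_MIN) / V_TABLE_STEP)) + 1
    tables = np.empty((n_types, n_v, N_TABLE_COLS), dtype=np.float64)
    for k in range(n_types):
        _fill_table(tables[k], dt, float(tau_d_scales[k]), float(tau_f_scales[k]))
    return tables


# ------------------------------------------------------------------
# Single-cell integration (direct rate evaluation, no tables)
# ------------------------------------------------------------------
@njit(cache=True)
def integrate_single_cell(y0, gna, gsi_scale, tau_d_scale, tau_f_scale, gk_scale,
                          stim_times, stim_amp, stim_dur, dt, n_steps, record_every):
    """Rush-Larsen / forward-Euler integration of one cell.

    ``y0`` is the 8-vector (V, m, h, j, d, f, X, Cai).  Returns the recorded
    voltage trace (every ``record_every`` steps, starting at step 0) and the
    final state.
    """
    v, m, h, j, d, f, x, cai = (
        y0[0], y0[1], y0[2], y0[3], y0[4], y0[5], y0[6], y0[7],
    )
    n_rec = n_steps // record_every + 1
    trace = np.empty(n_rec, dtype=np.float64)
    trace[0] = v
    n_stim = stim_times.shape[0]
    for step in range(n_steps):
        t = step * dt
        i_stim = 0.0
        for s in range(n_stim):
            if stim_times[s] <= t < stim_times[s] + stim_dur:
                i_stim = stim_amp
                break
        am, bm = rates_m(v)
        ah, bh = rates_h(v)
        aj, bj = rates_j(v)
        ad, bd = rates_d(v)
        af, bf = rates_f(v)
        ax, bx = rates_x(v)

        ina = gna * m * m * m * h * j * (v - E_NA)
        isi = G_SI_BAR * gsi_scale * d * f * (v - e_si(cai))
        ik = G_K_BAR * gk_scale * x * xi_factor(v) * (v - E_K)
        itot = ina + isi + ik + i_static(v)

        v = v + dt * (-(itot - i_stim))
        m = _rl_update(m, am, bm, dt, 1.0)
        h = _rl_update(h, ah, bh, dt, 1.0)
        j = _rl_update(j, aj, bj, dt, 1.0)
        d = _rl_update(d, ad, bd, dt, tau_d_scale)
        f = _rl_update(f, af, bf, dt, tau_f_scale)
        x = _rl_update(x, ax, bx, dt, 1.0)
        cai = cai + dt * (-1.0e-4 * isi + 0.07 * (CAI_REST - cai))
        if cai < 1.0e-7:
            cai = 1.0e-7

        if (step + 1) % record_every == 0:
            trace[(step + 1) // record_every] = v

    out_state = np.array([v, m, h, j, d, f, x, cai])
    return trace, out_state


@njit(cache=True)
def _rl_update(gate, a, b, dt, tau_scale):
    inf = a / (a + b)
    return inf + (gate - inf) * math.exp(-dt * (a + b) / tau_scale)
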