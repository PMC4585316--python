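"""Numba kernels for strand propagation.

Operator splitting per time step: explicit membrane update (Rush-Larsen
gates from per-cell-type lookup tables, forward Euler for V and [Ca]i),
then implicit backward-Euler integration of the resistive coupling as two
one-dimensional tridiagonal solves (x then y).  The tridiagonal systems are
constant in time, so their Thomas-algorithm factors are computed once.

dV/dt is tracked per node as the total voltage change per step; the
earliest activation time of a node is the time of its maximal dV/dt.
"""

import math

import numpy as np
from numba import njit

from ._lr1core import (
    E_K,
    E_NA,
    G_K_BAR,
    G_SI_BAR,
    CAI_REST,
    V_TABLE_MIN,
    V_TABLE_STEP,
)


@njit(cache=True)
def thomas_prefactor(sub, diag, sup):
    """In-place LU-style factors for a constant tridiagonal system.

    Returns (mfac, beta): forward-elimination multipliers and modified
    diagonal, both same length as ``diag``.
    """
    n = diag.shape[0]
    mfac = np.zeros(n)
    beta = np.empty(n)
    beta[0] = diag[0]
    for i in range(1, n):
        mfac[i] = sub[i] / beta[i - 1]
        beta[i] = diag[i] - mfac[i] * sup[i - 1]
    return mfac, beta


@njit(cache=True)
def _solve_row(vrow, mfac, beta, sup, work):
    n = vrow.shape[0]
    work[0] = vrow[0]
    for i in range(1, n):
        work[i] = vrow[i] - mfac[i] * work[i - 1]
    vrow[n - 1] = work[n - 1] / beta[n - 1]
    for i in range(n - 2, -1, -1):
        vrow[i] = (work[i] - sup[i] * vrow[i + 1]) / beta[i]


@njit(cache=True)
def diffusion_sweep(vm, mx, bx, sx, my, by, sy, workx, worky):
    """One implicit diffusion step: x-sweep over rows, y-sweep over columns."""
    ny, nx = vm.shape
    for iy in range(ny):
        _solve_row(vm[iy, :], mx[iy], bx[iy], sx[iy], workx)
    colbuf = worky[:ny]
    rhs = worky[ny : 2 * ny]
    for ix in range(nx):
        for iy in range(ny):
            colbuf[iy] = vm[iy, ix]
        _solve_row(colbuf, my[ix], by[ix], sy[ix], rhs)
        for iy in range(ny):
            vm[iy, ix] = colbuf[iy]


@njit(cache=True)
def _membrane_step(vm, gm, gh, gj, gd, gf, gx_, cai, ctype, tables,
                   gna3, gsi3, gk3, dt, stim_cols, i_stim):
    ny, nx = vm.shape
    inv_dv = 1.0 / V_TABLE_STEP
    n_v = tables.shape[1]
    for iy in range(ny):
        for ix in range(nx):
            v = vm[iy, ix]
            t = ctype[iy, ix]
            pos = (v - V_TABLE_MIN) * inv_dv
            if pos < 0.0:
                pos = 0.0
            elif pos > n_v - 1.001:
                pos = n_v - 1.001
            i0 = int(pos)
            w = pos - i0
            tab0 = tables[t, i0]
            tab1 = tables[t, i0 + 1]

            m = gm[iy, ix]
            h = gh[iy, ix]
            j = gj[iy, ix]
            d = gd[iy, ix]
            f = gf[iy, ix]
            x = gx_[iy, ix]
            ca = cai[iy, ix]

            ina = gna3[t] * m * m * m * h * j * (v - E_NA)
            esi = 7.7 - 13.0287 * math.log(ca)
            isi = G_SI_BAR * gsi3[t] * d * f * (v - esi)
            xi = tab0[12] * (1.0 - w) + tab1[12] * w
            ik = G_K_BAR * gk3[t] * x * xi * (v - E_K)
            istatic = tab0[13] * (1.0 - w) + tab1[13] * w
            itot = ina + isi + ik + istatic

            stim = i_stim if ix < stim_cols else 0.0
            vm[iy, ix] = v + dt * (stim - itot)

            minf = tab0[0] * (1.0 - w) + tab1[0] * w
            gm[iy, ix] = minf + (m - minf) * (tab0[1] * (1.0 - w) + tab1[1] * w)
            hinf = tab0[2] * (1.0 - w) + tab1[2] * w
            gh[iy, ix] = hinf + (h - hinf) * (tab0[3] * (1.0 - w) + tab1[3] * w)
            jinf = tab0[4] * (1.0 - w) + tab1[4] * w
            gj[iy, ix] = jinf + (j - jinf) * (tab0[5] * (1.0 - w) + tab1[5] * w)
            dinf = tab0[6] * (1.0 - w) + tab1[6] * w
            gd[iy, ix] = dinf + (d - dinf) * (tab0[7] * (1.0 - w) + tab1[7] * w)
            finf = tab0[8] * (1.0 - w) + tab1[8] * w
            gf[iy, ix] = finf + (f - finf) * (tab0[9] * (1.0 - w) + tab1[9] * w)
            xinf = tab0[10] * (1.0 - w) + tab1[10] * w
            gx_[iy, ix] = xinf + (x - xinf) * (tab0[11] * (1.0 - w) + tab1[11] * w)
            ca = ca + dt * (-1.0e-4 * isi + 0.07 * (CAI_REST - ca))
            cai[iy, ix] = ca if ca > 1.0e-7 else 1.0e-7


@njit(cache=True)
def propagate_beat(vm, gm, gh, gj, gd, gf, gx_, cai, ctype, tables,
                   gna3, gsi3, gk3,
                   mx, bx, sx, my, by, sy,
                   stim_cols, stim_amp, stim_dur,
                   dt, n_steps, act_thresh, sentinel_col, check_every,
                   margin_steps, eat, dvdtmax, snap_every, snaps):
    """Single stimulated beat; returns (steps_run, aborted).

    ``eat`` (ms, -1 where never activated) and ``dvdtmax`` (mV/ms) must be
    pre-initialized to -1 and 0.  Early exit once every column up to
    ``sentinel_col`` contains an activated node, plus a settle margin.
    With ``snap_every`` > 0 the voltage field is copied into ``snaps``
    (shape (n_snaps, ny, nx)) every ``snap_every`` steps, starting at 0.
    """
    ny, nx = vm.shape
    vprev = np.empty_like(vm)
    workx = np.empty(nx)
    worky = np.empty(2 * ny)
    countdown = -1
    steps_run = n_steps
    aborted = False
    n_snaps = snaps.shape[0]
    for step in range(n_steps):
        t_now = step * dt
        if snap_every > 0 and step % snap_every == 0:
            k = step // snap_every
            if k < n_snaps:
                snaps[k, :, :] = vm
        i_stim = stim_amp if t_now < stim_dur else 0.0
        vprev[:, :] = vm
        _membrane_step(vm, gm, gh, gj, gd, gf, gx_, cai, ctype, tables,
                       gna3, gsi3, gk3, dt, stim_cols, i_stim)
        diffusion_sweep(vm, mx, bx, sx, my, by, sy, workx, worky)
        inv_dt = 1.0 / dt
        for iy in range(ny):
            for ix in range(nx):
                dv = (vm[iy, ix] - vprev[iy, ix]) * inv_dt
                if dv > dvdtmax[iy, ix]:
                    dvdtmax[iy, ix] = dv
                    eat[iy, ix] = t_now + dt

        if countdown > 0:
            countdown -= 1
            if countdown == 0:
                steps_run = step + 1
                break
        elif countdown < 0 and (step + 1) % check_every == 0:
            if not np.all(np.isfinite(vm)) or np.max(np.abs(vm)) > 200.0:
                aborted = True
                steps_run = step + 1
                break
            all_act = True
            for ix in range(sentinel_col + 1):
                col_act = False
                for iy in range(ny):
                    if dvdtmax[iy, ix] > act_thresh:
                        col_act = True
                        break
                if not col_act:
                    all_act = False
                    break
            if all_act:
                countdown = margin_steps
    return steps_run, aborted


@njit(cache=True)
def integrate_paced(vm, gm, gh, gj, gd, gf, gx_, cai, ctype, tables,
                    gna3, gsi3, gk3,
                    mx, bx, sx, my, by, sy,
                    stim_cols, stim_amp, stim_dur, stim_times,
                    dt, n_steps):
    """Pace without activation tracking (state conditioning before analysis)."""
    ny, nx = vm.shape
    workx = np.empty(nx)
    worky = np.empty(2 * ny)
    n_stim = stim_times.shape[0]
    for step in range(n_steps):
        t_now = step * dt
        i_stim = 0.0
        for s in range(n_stim):
            if stim_times[s] <= t_now < stim_times[s] + stim_dur:
                i_stim = stim_amp
                break
        _membrane_step(vm, gm, gh, gj, gd, gf, gx_, cai, ctype, tables,
                       gna3, gsi3, gk3, dt, stim_cols, i_stim)
        diffusion_sweep(vm, mx, bx, sx, my, by, sy, workx, worky)


@njit(cache=True)
def run_ramp(vm, gm, gh, gj, gd, gf, gx_, cai, ctype, tables,
             gna3, gsi3, gk3,
             mx, bx, sx, my, by, sy,
             stim_cols, stim_amp, stim_dur, stim_times,
             dt, act_thresh, distal_col0):
    """Descending cycle-length pacing; per-beat distal activation flags.

    Beat k occupies [stim_times[k], stim_times[k+1]); the run stops one full
    beat after the first beat whose distal region (columns >= distal_col0)
    never exceeds ``act_thresh``.  Returns a uint8 success array (2 =
    not-evaluated/stopped-early).
    """
    ny, nx = vm.shape
    vprev = np.empty_like(vm)
    workx = np.empty(nx)
    worky = np.empty(2 * ny)
    n_beats = stim_times.shape[0]
    beat_max = np.zeros(n_beats)
    success = np.full(n_beats, 2, dtype=np.uint8)
    t_end = stim_times[n_beats - 1] + 300.0
    n_steps = int(t_end / dt)
    kb = 0
    inv_dt = 1.0 / dt
    for step in range(n_steps):
        t_now = step * dt
        while kb + 1 < n_beats and t_now >= stim_times[kb + 1]:
            success[kb] = 1 if beat_max[kb] > act_thresh else 0
            if success[kb] == 0:
                return success
            kb += 1
        i_stim = stim_amp if stim_times[kb] <= t_now < stim_times[kb] + stim_dur else 0.0
        vprev[:, :] = vm
        _membrane_step(vm, gm, gh, gj, gd, gf, gx_, cai, ctype, tables,
                       gna3, gsi3, gk3, dt, stim_cols, i_stim)
        diffusion_sweep(vm, mx, bx, sx, my, by, sy, workx, worky)
        local_max = 0.0
        for iy in range(ny):
            for ix in range(distal_col0, nx):
                dv = (vm[iy, ix] - vprev[iy, ix]) * inv_dt
                if dv > local_max:
                    local_max = dv
        if local_max > beat_max[kb]:
            beat_max[kb] = local_max
    success[kb] = 1 if beat_max[kb] > act_thresh else 0
    return success
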