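import math

import numpy as np
import pytest

from strandcv import _lr1core as core
from strandcv.lr1 import (
    DEFAULT_CELL_TYPES,
    APTrace,
    CellTypeParams,
    MembraneState,
    apd90,
    lr1_derivatives,
    max_upstroke_velocity,
    resting_state,
    simulate_single_cell,
)

# ----------------------------------------------------------------------
# Independent transcription of the LR1 rate equations, used as the oracle
# against the package's implementation.  Kept deliberately separate in
# style (dict-based, no reuse of package helpers).
# ----------------------------------------------------------------------
def oracle_rates(v):
    r = {}
    dv = v + 47.13
    r["am"] = 3.2 if abs(dv) < 1e-7 else 0.32 * dv / (1 - math.exp(-0.1 * dv))
    r["bm"] = 0.08 * math.exp(-v / 11)
    if v < -40:
        r["ah"] = 0.135 * math.exp((80 + v) / -6.8)
        r["bh"] = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        r["aj"] = (
            (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1 + math.exp(0.311 * (v + 79.23)))
        )
        r["bj"] = (
            0.1212 * math.exp(-0.01052 * v) / (1 + math.exp(-0.1378 * (v + 40.14)))
        )
    else:
        r["ah"] = 0.0
        r["bh"] = 1 / (0.13 * (1 + math.exp((v + 10.66) / -11.1)))
        r["aj"] = 0.0
        r["bj"] = (
            0.3 * math.exp(-2.535e-7 * v) / (1 + math.exp(-0.1 * (v + 32)))
        )
    r["ad"] = 0.095 * math.exp(-0.01 * (v - 5)) / (1 + math.exp(-0.072 * (v - 5)))
    r["bd"] = 0.07 * math.exp(-0.017 * (v + 44)) / (1 + math.exp(0.05 * (v + 44)))
    r["af"] = 0.012 * math.exp(-0.008 * (v + 28)) / (1 + math.exp(0.15 * (v + 28)))
    r["bf"] = 0.0065 * math.exp(-0.02 * (v + 30)) / (1 + math.exp(-0.2 * (v + 30)))
    r["ax"] = 0.0005 * math.exp(0.083 * (v + 50)) / (1 + math.exp(0.057 * (v + 50)))
    r["bx"] = 0.0013 * math.exp(-0.06 * (v + 20)) / (1 + math.exp(-0.04 * (v + 20)))
    return r


def oracle_derivatives(y, p: CellTypeParams, i_stim=0.0):
    v, m, h, j, d, f, x, cai = y
    r = oracle_rates(v)
    e_na = 54.4
    rtf = 26.73
    e_k1 = rtf * math.log(5.4 / 145.0)
    ina = p.gna_max * m**3 * h * j * (v - e_na)
    esi = 7.7 - 13.0287 * math.log(cai)
    isi = 0.09 * p.gsi_scale * d * f * (v - esi)
    if v <= -100:
        xi = 1.0
    elif abs(v + 77) < 1e-7:
        xi = 2.837 * 0.04 / math.exp(0.04 * (v + 35))
    else:
        xi = (
            2.837
            * (math.exp(0.04 * (v + 77)) - 1)
            / ((v + 77) * math.exp(0.04 * (v + 35)))
        )
    ik = 0.282 * p.gk_scale * x * xi * (v + 77.0)
    ak1 = 1.02 / (1 + math.exp(0.2385 * (v - e_k1 - 59.215)))
    bk1 = (
        0.49124 * math.exp(0.08032 * (v - e_k1 + 5.476))
        + math.exp(0.06175 * (v - e_k1 - 594.31))
    ) / (1 + math.exp(-0.5143 * (v - e_k1 + 4.753)))
    ik1 = 0.6047 * ak1 / (ak1 + bk1) * (v - e_k1)
    ikp = 0.0183 * (v - e_k1) / (1 + math.exp((7.488 - v) / 5.98))
    ib = 0.03921 * (v + 59.87)
    itot = ina + isi + ik + ik1 + ikp + ib
    return np.array(
        [
            -(itot - i_stim),
            r["am"] * (1 - m) - r["bm"] * m,
            r["ah"] * (1 - h) - r["bh"] * h,
            r["aj"] * (1 - j) - r["bj"] * j,
            (r["ad"] * (1 - d) - r["bd"] * d) / p.tau_d_scale,
            (r["af"] * (1 - f) - r["bf"] * f) / p.tau_f_scale,
            r["ax"] * (1 - x) - r["bx"] * x,
            -1e-4 * isi + 0.07 * (1e-4 - cai),
        ]
    )


def _random_states(rng, n):
    for _ in range(n):
        yield np.array(
            [
                rng.uniform(-90, 40),
                *rng.uniform(0.001, 0.999, 6),
                rng.uniform(1e-5, 5e-3),
            ]
        )


def test_derivatives_match_independent_oracle(rng):
    """Package RHS equals an independently transcribed LR1 at 100 states."""
    p = DEFAULT_CELL_TYPES["HE_SCM"]
    for y in _random_states(rng, 100):
        got = lr1_derivatives(MembraneState.from_array(y), p, i_stim=3.0)
        want = oracle_derivatives(y, p, i_stim=3.0)
        assert np.all(np.abs(got - want) <= 1e-9 * np.maximum(1.0, np.abs(want)))


def test_kernel_rhs_matches_reference_path(rng):
    """The numba kernel transcription agrees with the NumPy reference RHS."""
    p = DEFAULT_CELL_TYPES["PCM"]
    for y in _random_states(rng, 50):
        got = np.array(
            core.cell_derivatives(
                *y, p.gna_max, p.gsi_scale, p.tau_d_scale, p.tau_f_scale,
                p.gk_scale, 0.0,
            )
        )
        want = lr1_derivatives(MembraneState.from_array(y), p)
        assert np.all(np.abs(got - want) <= 1e-9 * np.maximum(1.0, np.abs(want)))


def test_rest_is_stationary():
    """At the settled resting state all derivatives nearly vanish."""
    p = DEFAULT_CELL_TYPES["PCM"]
    rest = resting_state(p)
    dy = lr1_derivatives(rest, p)
    assert abs(dy[0]) < 1e-3  # V/s
    assert rest.v == pytest.approx(-84.6, abs=1.0)


def test_ina_linear_in_gna():
    state = MembraneState(v=-30.0, m=0.5, h=0.4, j=0.5, d=0.01, f=0.9,
                          x=0.01, cai=2e-4)
    p1 = DEFAULT_CELL_TYPES["PCM"]
    p2 = p1.with_gna(2 * p1.gna_max)
    dv1 = lr1_derivatives(state, p1)[0]
    dv2 = lr1_derivatives(state, p2)[0]
    # doubling gNa adds exactly one extra I_Na to the charge balance
    extra = -(p1.gna_max * state.m**3 * state.h * state.j * (state.v - 54.4))
    assert dv2 - dv1 == pytest.approx(extra, rel=1e-12)


def test_single_cell_ap_and_subthreshold():
    p = DEFAULT_CELL_TYPES["PCM"]
    tr = simulate_single_cell(p, beats=1)
    assert tr.elicited
    assert tr.v.max() - tr.v[0] > 100.0  # overshoot amplitude above rest
    quiet = simulate_single_cell(p, stim_amplitude=0.0, beats=1)
    assert not quiet.elicited
    assert np.max(np.abs(quiet.v - quiet.v[0])) < 1.0


def test_upstroke_ordering_and_gna_monotonicity():
    vels = []
    for gna in (2.0, 4.5, 8.0, 11.5, 16.0):
        p = DEFAULT_CELL_TYPES["PCM"].with_gna(gna)
        vels.append(max_upstroke_velocity(simulate_single_cell(p, beats=1)))
    assert np.all(np.diff(vels) > 0)


def test_gate_bounds_and_rest_drift():
    p = DEFAULT_CELL_TYPES["LE_SCM"]
    rest = resting_state(p)
    stim_times = np.arange(10) * 100.0
    trace, y_end = core.integrate_single_cell(
        rest.as_array(), p.gna_max, p.gsi_scale, p.tau_d_scale,
        p.tau_f_scale, p.gk_scale, stim_times, 40.0, 2.0, 0.005,
        int(1000 / 0.005), 200,
    )
    assert np.all(y_end[1:7] >= 0.0) and np.all(y_end[1:7] <= 1.0)
    # unstimulated drift over 1 s
    trace2, _ = core.integrate_single_cell(
        rest.as_array(), p.gna_max, p.gsi_scale, p.tau_d_scale,
        p.tau_f_scale, p.gk_scale, np.empty(0), 0.0, 0.0, 0.01,
        int(1000 / 0.01), 100,
    )
    assert np.max(np.abs(trace2 - trace2[0])) < 0.5


def test_max_upstroke_on_linear_ramp():
    """V rising 100 mV/ms reads exactly 100 V/s."""
    t = np.arange(0, 30, 0.01)
    v = -84.0 + 100.0 * t
    tr = APTrace(t, v, np.array([0.0]), stim_duration=2.0)
    assert max_upstroke_velocity(tr) == pytest.approx(100.0, rel=1e-9)


def test_apd90_near_calibration_target():
    tr = simulate_single_cell(DEFAULT_CELL_TYPES["PCM"], beats=1)
    assert 80.0 < apd90(tr) < 130.0


def test_trace_too_short_raises():
    t = np.arange(0, 5, 0.01)
    tr = APTrace(t, np.full_like(t, -84.0), np.array([0.0]), 2.0)
    with pytest.raises(ValueError):
        max_upstroke_velocity(tr, window_ms=20.0)
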