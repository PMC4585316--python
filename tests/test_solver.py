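from dataclasses import replace

import numpy as np
import pytest

from strandcv.analysis import cv_from_activation_map
from strandcv.architecture import (
    StrandGeometry,
    assign_cell_types,
    generate_architecture,
)
from strandcv.lr1 import DEFAULT_CELL_TYPES
from strandcv.solver import (
    CouplingScheme,
    PacingProtocol,
    build_network,
    calibrate_reference_coupling,
    diffusion_step,
    run_ramp_protocol,
    simulate_propagation,
)

from conftest import G_REF_SMALL, SMALL_GEO


def _cv(res, geo):
    return cv_from_activation_map(res.eat, geo).cv


class TestCouplingScheme:
    def test_baseline_matrix_minimum_rule(self):
        m = CouplingScheme.baseline().relative_matrix
        assert m[0, 0] == 1.0
        assert m[0, 1] == m[1, 0] == 0.0385  # PCM | LE-SCM
        assert m[0, 2] == m[2, 0] == 0.0205  # PCM | HE-SCM
        assert m[1, 2] == 0.0205  # LE | HE: minimum of pair

    def test_enhanced_matrix(self):
        m = CouplingScheme.enhanced().relative_matrix
        assert m[0, 1] == 0.1538 and m[0, 2] == 0.0821
        assert m[1, 2] == 0.0385  # raised to the LE level
        assert m[1, 1] == 0.0385 and m[2, 2] == 0.0205

    def test_min_rule_violation_rejected(self):
        bad = np.array([[1.0, 0.5, 0.02], [0.5, 0.04, 0.02], [0.02, 0.02, 0.02]])
        with pytest.raises(ValueError):
            CouplingScheme(bad, rule="min_of_pair")

    def test_asymmetric_rejected(self):
        bad = np.array([[1.0, 0.3, 0.2], [0.1, 0.5, 0.2], [0.2, 0.2, 0.4]])
        with pytest.raises(ValueError):
            CouplingScheme(bad)


class TestBuildNetwork:
    def test_edge_conductances(self):
        arch = generate_architecture(SMALL_GEO, jitter=0.0, seed=0)
        arch = assign_cell_types(arch, 0.0, seed=0)
        g_ref = 0.04
        net = build_network(arch, CouplingScheme.baseline(g_ref), intra_g=0.5)
        vals = np.unique(np.concatenate([net.gx.ravel(), net.gy.ravel()]))
        assert set(np.round(vals, 10)) == {g_ref, 0.5}

    def test_heterocellular_edges_use_pair_factor(self):
        arch = generate_architecture(SMALL_GEO, jitter=0.0, seed=0)
        # force alternate cells LE so PCM|LE interfaces exist
        ct = {cid: ("LE_SCM" if cid % 2 else "PCM") for cid in arch.cell_type}
        arch.cell_type = ct
        net = build_network(arch, CouplingScheme.baseline(1.0), intra_g=0.5)
        ids = arch.cell_id_grid
        boundary = ids[:, 1:] != ids[:, :-1]
        types = arch.type_index_grid()
        hetero = boundary & (types[:, 1:] != types[:, :-1])
        assert np.allclose(net.gx[hetero], 0.0385)


def test_diffusion_conserves_total_voltage(small_arch):
    net = build_network(small_arch, CouplingScheme.baseline(G_REF_SMALL))
    rng = np.random.default_rng(0)
    f = rng.normal(size=(SMALL_GEO.ny, SMALL_GEO.nx)) * 50
    g = diffusion_step(net, f, dt=0.005)
    assert g.sum() == pytest.approx(f.sum(), rel=1e-12)


def test_voltage_history_recording(small_arch):
    """Decimated V snapshots start at rest and show the propagated wave."""
    net = build_network(small_arch, CouplingScheme.baseline(G_REF_SMALL))
    res = simulate_propagation(net, record_v_every_ms=1.0)
    assert res.v_history is not None and res.v_history_dt == pytest.approx(1.0)
    assert res.v_history.shape[1:] == res.eat.shape
    assert np.all(np.abs(res.v_history[0] + 84.6) < 1.0)  # starts at rest
    assert res.v_history[-1].max() > 0.0  # depolarized tissue in-beat


def test_seed_determinism(small_arch):
    net = build_network(small_arch, CouplingScheme.baseline(G_REF_SMALL))
    r1 = simulate_propagation(net)
    r2 = simulate_propagation(net)
    assert np.array_equal(
        np.nan_to_num(r1.eat, nan=-9), np.nan_to_num(r2.eat, nan=-9)
    )
    assert np.array_equal(r1.dvdtmax, r2.dvdtmax)


def test_disconnection_blocks_distal_half(small_arch):
    net = build_network(small_arch, CouplingScheme.baseline(G_REF_SMALL))
    cut = SMALL_GEO.nx // 2
    net.gx[:, cut] = 1e-9  # sever the strand mid-way
    res = simulate_propagation(net)
    assert res.blocked
    assert not res.activated[:, cut + 5 :].any()


def test_cv_monotone_in_g_ref(small_arch):
    cvs = []
    for g in (0.02, 0.05, 0.12):
        net = build_network(small_arch, CouplingScheme.baseline(g))
        cvs.append(_cv(simulate_propagation(net), SMALL_GEO))
    assert cvs[0] < cvs[1] < cvs[2]


def test_cv_monotone_in_gna(small_arch):
    net = build_network(small_arch, CouplingScheme.baseline(G_REF_SMALL))
    cvs = []
    for gna in (4.5, 9.0, 13.5):
        params = {k: v.with_gna(gna) for k, v in DEFAULT_CELL_TYPES.items()}
        cvs.append(_cv(simulate_propagation(net, params), SMALL_GEO))
    assert cvs[0] < cvs[1] < cvs[2]


def test_cv_scales_as_sqrt_coupling_in_continuum_limit():
    """Uniformly scaling all conductances by 4 doubles CV (within 15%)."""
    geo = StrandGeometry(length=3000.0, width=15.0, node_spacing=5.0)
    arch = generate_architecture(geo, jitter=0.0, seed=0)
    cvs = []
    for g in (0.125, 0.5):
        net = build_network(arch, CouplingScheme.baseline(1.0), intra_g=g)
        net.gx[:] = g
        net.gy[:] = g
        cvs.append(_cv(simulate_propagation(net), geo))
    assert cvs[1] / cvs[0] == pytest.approx(2.0, rel=0.15)


def test_refinement_dt_and_spacing():
    """Halving dt and node spacing changes the strand CV by < 3% each."""
    geo = StrandGeometry(length=1000.0, width=30.0, node_spacing=5.0)
    arch = generate_architecture(geo, jitter=0.0, seed=0)
    net = build_network(arch, CouplingScheme.baseline(G_REF_SMALL))
    cv0 = _cv(simulate_propagation(net, dt=0.005), geo)
    cv_dt = _cv(simulate_propagation(net, dt=0.0025), geo)
    assert abs(cv_dt - cv0) / cv0 < 0.03

    geo_f = StrandGeometry(length=1000.0, width=30.0, node_spacing=2.5)
    arch_f = generate_architecture(geo_f, jitter=0.0, seed=0)
    # junctional conductance per unit interface length is fixed, so the
    # per-edge value halves with the spacing; the myoplasmic sheet
    # conductance of a square tile is spacing-independent
    net_f = build_network(arch_f, CouplingScheme.baseline(G_REF_SMALL / 2))
    cv_h = _cv(simulate_propagation(net_f), geo_f)
    assert abs(cv_h - cv0) / cv0 < 0.03


def test_first_beat_matches_second_beat():
    """CV of the first beat from rest equals a conditioned beat at CL 300."""
    geo = StrandGeometry(length=1000.0, width=30.0, node_spacing=5.0)
    arch = generate_architecture(geo, seed=2)
    net = build_network(arch, CouplingScheme.baseline(G_REF_SMALL))
    cv1 = _cv(simulate_propagation(net), geo)
    cv2 = _cv(
        simulate_propagation(net, protocol=PacingProtocol(n_beats=2)), geo
    )
    assert cv2 == pytest.approx(cv1, rel=0.01)


class TestCalibration:
    def test_round_trip_recovers_g_ref(self):
        factory = lambda s: generate_architecture(SMALL_GEO, seed=s)  # noqa
        net = build_network(factory(0), CouplingScheme.baseline(0.05))
        target = _cv(simulate_propagation(net), SMALL_GEO)
        g, achieved = calibrate_reference_coupling(
            target, arch_factory=factory, tolerance=0.05, seeds=(0,),
        )
        assert g == pytest.approx(0.05, rel=0.05)
        assert achieved == pytest.approx(target, abs=0.05)

    def test_monotone_in_target(self):
        factory = lambda s: generate_architecture(SMALL_GEO, seed=s)  # noqa
        g1, _ = calibrate_reference_coupling(
            20.0, arch_factory=factory, tolerance=0.2, seeds=(0,)
        )
        g2, _ = calibrate_reference_coupling(
            30.0, arch_factory=factory, tolerance=0.2, seeds=(0,)
        )
        assert g2 > g1

    def test_unreachable_target_raises(self):
        factory = lambda s: generate_architecture(SMALL_GEO, seed=s)  # noqa
        with pytest.raises(RuntimeError):
            calibrate_reference_coupling(
                500.0, arch_factory=factory, seeds=(0,)
            )


class TestRamp:
    def _small_net(self):
        geo = StrandGeometry(length=600.0, width=30.0, node_spacing=5.0)
        arch = generate_architecture(geo, seed=1)
        return build_network(arch, CouplingScheme.baseline(G_REF_SMALL))

    def test_erp_tracks_repolarization(self):
        """Cells with a longer action potential fail the descending ramp at
        a longer cycle length.  (LR1's strong rate adaptation places the
        ramp ERP well below the slow-rate APD90; see docs/methods.md.)"""
        proto = PacingProtocol(mode="ramp", cl_start=250.0, cl_end=30.0,
                               ramp_rate=6000.0)
        long_ap = {
            k: replace(v, gsi_scale=0.5, gk_scale=1.5)
            for k, v in DEFAULT_CELL_TYPES.items()
        }
        res_long = run_ramp_protocol(self._small_net(), long_ap, proto)
        res_short = run_ramp_protocol(self._small_net(), protocol=proto)
        assert not res_long.censored
        assert 30.0 <= res_long.erp_ms <= 90.0
        # short-AP default cells remain capturable at least as far down
        floor_long = res_long.cl_at_failure
        assert res_short.censored or res_short.cl_at_failure < floor_long

    def test_ramp_below_refractoriness_fails_immediately(self):
        proto = PacingProtocol(mode="ramp", cl_start=60.0, cl_end=40.0,
                               ramp_rate=6000.0)
        res = run_ramp_protocol(self._small_net(), protocol=proto)
        assert not res.censored
        assert res.failed_beat is not None and res.failed_beat <= 2

    def test_no_failure_is_censored(self):
        proto = PacingProtocol(mode="ramp", cl_start=320.0, cl_end=300.0,
                               ramp_rate=6000.0)
        res = run_ramp_protocol(self._small_net(), protocol=proto)
        assert res.censored and res.erp_ms is None
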