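import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandcv import mea
from strandcv.analysis import cv_from_activation_map
from strandcv.architecture import StrandGeometry


def test_detection_recovers_truth_clean():
    rec = mea.generate_synthetic_recording(true_cv=35.0, beats=3, noise_sd=0.0)
    acts = mea.detect_activation_times(rec)
    truth = np.array(rec.ground_truth["activation_times_ms"])
    assert np.nanmax(np.abs(acts - truth)) <= 0.1  # within one sample


def test_flat_noise_trace_all_missing():
    rec = mea.generate_synthetic_recording(true_cv=35.0, beats=2, noise_sd=0.0)
    rng = np.random.default_rng(0)
    rec.traces = rng.normal(0, 0.02, rec.traces.shape)
    acts = mea.detect_activation_times(rec)
    assert np.isnan(acts).all()


def test_uniform_delays_exact_cv():
    """1.0-ms delays at 0.5-mm spacing read exactly 50 cm/s."""
    acts = np.arange(12)[None, :] * 1.0
    cv = mea.cv_per_beat(acts, np.arange(12) * 0.5)
    assert cv[0] == pytest.approx(50.0, rel=1e-12)


def test_interelectrode_time_at_control_velocity():
    """At 34.9 cm/s the 0.5-mm conduction time is 1.433 ms."""
    rec = mea.generate_synthetic_recording(true_cv=34.9, beats=2, noise_sd=0.0)
    acts = mea.detect_activation_times(rec)
    dts = np.diff(acts[0])
    assert np.allclose(dts, 0.5 / (34.9 / 100.0), atol=0.05)


def test_steady_state_cv_within_2pct():
    """33 noisy, jittered beats recover a 20 cm/s truth within 2%."""
    rec = mea.generate_synthetic_recording(
        true_cv=20.0, beats=33, cl_ms=300.0, jitter_sd_ms=0.1,
        noise_sd=0.02, seed=9,
    )
    acts = mea.detect_activation_times(rec)
    cv = mea.steady_state_cv(acts, rec.electrode_positions, rec.stim_times)
    assert cv == pytest.approx(20.0, rel=0.02)


def test_scm_regime_velocity_recovered():
    rec = mea.generate_synthetic_recording(true_cv=5.5, beats=3, seed=2)
    acts = mea.detect_activation_times(rec)
    cvs = mea.cv_per_beat(acts, rec.electrode_positions)
    assert np.nanmean(cvs) == pytest.approx(5.5, rel=0.02)


def test_detector_rms_error_within_one_sample_at_snr20():
    """RMS timing error <= 1 sample (0.1 ms) at SNR 20, 200 beats."""
    errs = []
    for seed in range(40):
        rec = mea.generate_synthetic_recording(
            true_cv=35.0, beats=5, noise_sd=0.05, seed=seed
        )
        acts = mea.detect_activation_times(rec)
        truth = np.array(rec.ground_truth["activation_times_ms"])
        errs.append((acts - truth).ravel())
    e = np.concatenate(errs)
    assert e.size >= 200 * 12
    assert np.sqrt(np.nanmean(e**2)) <= 0.1


class TestCVarCT:
    def test_zero_for_uniform(self):
        acts = np.arange(12)[None, :] * 1.433
        assert mea.cvarct(acts).cvarct == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        """Intervals [1,1,1,3] ms: population SD/mean = 0.866/1.5 = 0.577."""
        acts = np.cumsum([0.0, 1.0, 1.0, 1.0, 3.0])[None, :]
        got = mea.cvarct(acts).cvarct
        assert got == pytest.approx(np.std([1, 1, 1, 3]) / 1.5, rel=1e-12)
        assert got == pytest.approx(0.5774, abs=1e-4)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_scale_invariance(self, c):
        acts = np.cumsum([0.0, 1.0, 2.0, 1.5, 0.7, 1.2])[None, :]
        a = mea.cvarct(acts).cvarct
        b = mea.cvarct(acts * c).cvarct
        assert b == pytest.approx(a, rel=1e-9)

    def test_slow_segment_raises_index(self):
        uni = mea.generate_synthetic_recording(true_cv=20.0, beats=3, seed=0)
        mult = np.ones(11)
        mult[5] = 4.0
        het = mea.generate_synthetic_recording(
            true_cv=20.0, segment_delay_multipliers=mult, beats=3, seed=0
        )
        a = mea.cvarct(mea.detect_activation_times(uni)).cvarct
        b = mea.cvarct(mea.detect_activation_times(het)).cvarct
        assert b > a

    def test_uniform_synthetic_recording_near_zero(self):
        rec = mea.generate_synthetic_recording(true_cv=35.0, beats=3,
                                               noise_sd=0.0)
        acts = mea.detect_activation_times(rec)
        assert mea.cvarct(acts).cvarct < 0.01


class TestERP:
    def test_definition_on_flags(self):
        stim = np.array([0.0, 300.0, 580.0, 840.0, 1080.0])
        ok = np.array([1, 1, 1, 0, 0], bool)
        erp, censored = mea.erp_from_ramp(ok, stim)
        assert not censored
        assert erp == pytest.approx(580.0 - 300.0)

    def test_no_failure_sentinel(self):
        erp, censored = mea.erp_from_ramp(np.ones(5, bool), np.arange(5) * 300.0)
        assert censored and erp is None

    def test_synthetic_ramp_refractory_cutoff(self):
        """A 120-ms refractory cutoff yields an ERP near 120 ms."""
        cls = [300.0]
        while cls[-1] > 80.0:
            cls.append(cls[-1] * 0.93)
        stim = np.concatenate([[0.0], np.cumsum(cls)])
        rec = mea.generate_synthetic_recording(
            true_cv=30.0, stim_times=stim, refractory_cutoff_ms=120.0,
            noise_sd=0.0,
        )
        acts = mea.detect_activation_times(rec)
        ok = np.isfinite(acts).sum(axis=1) >= 3
        erp, censored = mea.erp_from_ramp(ok, stim)
        assert not censored
        assert erp == pytest.approx(120.0, abs=15.0)


def test_shared_regression_core_with_activation_maps():
    """Per-beat MEA CV equals the map regression on the same sequence."""
    geo = StrandGeometry(length=3000.0, width=5.0, node_spacing=5.0)
    x_um = np.arange(geo.nx) * geo.node_spacing
    times = x_um / (28.0 * 1e4) * 1e3 + 0.3 * np.sin(x_um / 200.0)
    est = cv_from_activation_map(times[None, :], geo, window=(0.0, 1.0))
    cv_mea = mea.cv_per_beat(times[None, :], x_um / 1000.0)[0]
    assert cv_mea == pytest.approx(est.cv, rel=1e-12)


def test_recording_roundtrip(tmp_path):
    rec = mea.generate_synthetic_recording(true_cv=25.0, beats=2, seed=1)
    rec.to_csv(tmp_path / "tr.csv", tmp_path / "meta.json")
    back = mea.MEARecording.from_csv(tmp_path / "tr.csv", tmp_path / "meta.json")
    assert back.sampling_rate == rec.sampling_rate
    assert np.allclose(back.traces, rec.traces, atol=1e-6)
    assert back.ground_truth["true_cv"] == 25.0
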