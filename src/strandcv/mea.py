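"""Multi-electrode-array signal analysis and its synthetic stand-in.

Strands are grown over a row of 12 extracellular electrodes spaced 0.5 mm
apart.  Activation at each electrode is the time of the minimum of the
(smoothed) first derivative of the extracellular electrogram; per-beat CV
is the inverse OLS slope of activation time vs electrode position, and
conduction heterogeneity is CVarCT: the coefficient of variation (population
SD / mean) of conduction times between successive electrodes (0 for
perfectly uniform conduction).

The synthetic generator places a biphasic deflection (difference of two
Gaussians, ~2 ms) at each electrode at the stimulus time plus cumulative
per-segment delays derived from a controllable true CV, with optional
per-segment delay multipliers, per-electrode jitter and additive noise.
Its ground truth is the steepest-downstroke time of each deflection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "MEARecording",
    "HeterogeneityIndex",
    "detect_activation_times",
    "cv_per_beat",
    "steady_state_cv",
    "cvarct",
    "erp_from_ramp",
    "generate_synthetic_recording",
]


@dataclass
class MEARecording:
    """Extracellular traces: one row of electrodes along the strand."""

    sampling_rate: float  # Hz
    electrode_positions: np.ndarray  # mm along the strand, increasing
    traces: np.ndarray  # (n_samples, n_electrodes) mV
    stim_times: np.ndarray  # ms, one per pacing stimulus
    ground_truth: dict | None = None  # generator metadata when synthetic

    def __post_init__(self):
        self.electrode_positions = np.asarray(self.electrode_positions, float)
        self.traces = np.asarray(self.traces, float)
        self.stim_times = np.asarray(self.stim_times, float)
        if self.traces.ndim != 2 or self.traces.shape[1] != len(
            self.electrode_positions
        ):
            raise ValueError("traces must be (n_samples, n_electrodes)")
        if np.any(np.diff(self.electrode_positions) <= 0):
            raise ValueError("electrode positions must be strictly increasing")

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.traces.shape[0]) * 1000.0 / self.sampling_rate

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = pd.DataFrame(
            self.traces,
            columns=[f"e{i}" for i in range(self.traces.shape[1])],
        )
        df.insert(0, "time_ms", self.t_ms)
        df.to_csv(path, index=False)
        if sidecar is not None:
            meta = {
                "sampling_rate_hz": self.sampling_rate,
                "electrode_positions_mm": self.electrode_positions.tolist(),
                "stim_times_ms": self.stim_times.tolist(),
                "ground_truth": self.ground_truth,
            }
            Path(sidecar).write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path, sidecar) -> "MEARecording":
        df = pd.read_csv(path)
        meta = json.loads(Path(sidecar).read_text())
        return cls(
            meta["sampling_rate_hz"],
            np.asarray(meta["electrode_positions_mm"]),
            df.drop(columns="time_ms").to_numpy(),
            np.asarray(meta["stim_times_ms"]),
            meta.get("ground_truth"),
        )


@dataclass(frozen=True)
class HeterogeneityIndex:
    """CVarCT: SD/mean of successive inter-electrode conduction times."""

    cvarct: float
    n_intervals: int

    def __post_init__(self):
        if self.cvarct < 0:
            raise ValueError("cvarct must be non-negative")


def detect_activation_times(
    rec: MEARecording,
    beat_windows: list[tuple[float, float]] | None = None,
    artifact_ms: float = 3.0,
    smooth_ms: float = 1.0,
    noise_factor: float = 8.0,
) -> np.ndarray:
    """Per-beat, per-electrode activation times (ms); NaN where missing.

    The activation time is the minimum of the Savitzky-Golay-smoothed first
    derivative inside each beat window, excluding ``artifact_ms`` after the
    stimulus, refined to sub-sample precision by parabolic interpolation.
    An electrode is marked missing for a beat when its peak downward slope
    does not exceed ``noise_factor`` times the derivative's robust noise
    level (median absolute deviation).
    """
    if rec.sampling_rate < 5000:
        raise ValueError("sampling rate must be at least 5 kHz")
    dt_ms = 1000.0 / rec.sampling_rate
    if beat_windows is None:
        edges = list(rec.stim_times) + [rec.t_ms[-1] + dt_ms]
        beat_windows = [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]

    win = max(5, int(round(smooth_ms / dt_ms)) | 1)  # odd window
    n_el = rec.traces.shape[1]
    out = np.full((len(beat_windows), n_el), np.nan)
    t = rec.t_ms
    for e in range(n_el):
        deriv = savgol_filter(
            rec.traces[:, e], win, polyorder=3, deriv=1, delta=dt_ms
        )
        mad = np.median(np.abs(deriv - np.median(deriv))) / 0.6745
        floor = noise_factor * max(mad, 1e-12)
        for b, (t0, t1) in enumerate(beat_windows):
            stim_in = rec.stim_times[(rec.stim_times >= t0 - 1e-9) & (rec.stim_times < t1)]
            t_start = (stim_in[0] + artifact_ms) if stim_in.size else t0
            sel = (t >= t_start) & (t < t1)
            idx = np.nonzero(sel)[0]
            if idx.size < 3:
                continue
            seg = deriv[idx]
            k = int(np.argmin(seg))
            if -seg[k] < floor:
                continue  # no deflection above noise: electrode missing
            i = idx[k]
            if 0 < i < len(deriv) - 1:  # parabolic sub-sample refinement
                y0, y1, y2 = deriv[i - 1], deriv[i], deriv[i + 1]
                denom = y0 - 2 * y1 + y2
                shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-30 else 0.0
                shift = float(np.clip(shift, -1, 1))
            else:
                shift = 0.0
            out[b, e] = t[i] + shift * dt_ms
    return out


def _regress_cv(times_ms: np.ndarray, positions_mm: np.ndarray) -> float | None:
    from .analysis import ols_line  # shared regression core

    ok = np.isfinite(times_ms)
    if ok.sum() < 3:
        return None
    slope = ols_line(positions_mm[ok], times_ms[ok])[0]  # ms per mm
    if slope <= 0:
        return None
    return 100.0 / slope  # mm/ms -> cm/s


def cv_per_beat(activations: np.ndarray, positions_mm: np.ndarray) -> np.ndarray:
    """Per-beat CV (cm/s) by OLS of activation time vs electrode position.

    Beats with fewer than three detected electrodes yield NaN.
    """
    positions_mm = np.asarray(positions_mm, float)
    out = np.full(activations.shape[0], np.nan)
    for b in range(activations.shape[0]):
        cv = _regress_cv(activations[b], positions_mm)
        if cv is not None:
            out[b] = cv
    return out


def steady_state_cv(
    activations: np.ndarray,
    positions_mm: np.ndarray,
    stim_times: np.ndarray,
    last_s: float = 10.0,
) -> float:
    """Mean CV over the beats whose stimulus falls in the final ``last_s``
    seconds of the pacing period."""
    cvs = cv_per_beat(activations, positions_mm)
    stim_times = np.asarray(stim_times, float)
    t_end = stim_times[-1]
    sel = stim_times >= t_end - last_s * 1000.0
    vals = cvs[sel[: len(cvs)]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no analyzable beats in the steady-state window")
    return float(np.mean(vals))


def cvarct(activations: np.ndarray, beats: slice | None = None) -> HeterogeneityIndex:
    """CVarCT of the analyzed beats (averaged over beats).

    Conduction times are differences of activation times at successive
    electrodes; the index is population-SD / mean per beat, averaged over
    beats with at least three finite intervals and positive mean.
    """
    acts = activations if activations.ndim == 2 else activations[None, :]
    if beats is not None:
        acts = acts[beats]
    vals = []
    for row in acts:
        ct = np.diff(row)
        ct = ct[np.isfinite(ct)]
        if ct.size < 3:
            continue
        mean = ct.mean()
        if mean <= 0:
            continue
        vals.append(np.std(ct) / mean)  # population SD convention
    if not vals:
        raise ValueError("no beat with >=3 finite conduction intervals")
    return HeterogeneityIndex(float(np.mean(vals)), int(acts.shape[1] - 1))


def erp_from_ramp(
    beat_success: np.ndarray, stim_times: np.ndarray
) -> tuple[float | None, bool]:
    """(ERP ms, censored) from per-beat propagation flags of a CL ramp.

    ERP is the interpulse interval between the last two propagated beats
    immediately before the first failure; censored=True (ERP <= final CL)
    when every beat propagated.
    """
    beat_success = np.asarray(beat_success, bool)
    stim_times = np.asarray(stim_times, float)
    fails = np.nonzero(~beat_success)[0]
    if fails.size == 0:
        return None, True
    k = int(fails[0])
    if k >= 2:
        return float(stim_times[k - 1] - stim_times[k - 2]), False
    return float(stim_times[1] - stim_times[0]), False


def _biphasic_template(t_ms: np.ndarray, center: float, width: float, amp: float):
    """Two-lobed deflection: difference of Gaussians with its steepest
    downstroke exactly at ``center``.  ``width`` is the approximate total
    pulse duration; the lobes sit at +/- width/4."""
    s = width / 4.0
    return amp * (
        np.exp(-((t_ms - center + s) ** 2) / (2 * s * s))
        - np.exp(-((t_ms - center - s) ** 2) / (2 * s * s))
    )


def generate_synthetic_recording(
    true_cv: float = 35.0,
    segment_delay_multipliers=None,
    noise_sd: float = 0.02,
    beats: int = 5,
    cl_ms: float = 300.0,
    n_electrodes: int = 12,
    spacing_mm: float = 0.5,
    sampling_rate: float = 10000.0,
    jitter_sd_ms: float = 0.0,
    template_width_ms: float = 2.0,
    amp_mv: float = 1.0,
    latency_ms: float = 6.0,
    refractory_cutoff_ms: float | None = None,
    stim_times: np.ndarray | None = None,
    seed: int = 0,
) -> MEARecording:
    """Synthetic paced MEA recording with known conduction.

    The wave reaches electrode i at ``stim + latency + sum of segment
    delays``; each nominal segment delay is spacing/true_cv times the
    corresponding multiplier.  With ``refractory_cutoff_ms`` set, a beat
    whose interval since the previous *propagated* beat is below the cutoff
    produces no deflections (conduction failure), emulating refractoriness
    in ramp protocols.
    """
    if true_cv <= 0:
        raise ValueError("true_cv must be positive")
    rng = np.random.default_rng(seed)
    if segment_delay_multipliers is None:
        segment_delay_multipliers = np.ones(n_electrodes - 1)
    mult = np.asarray(segment_delay_multipliers, float)
    if mult.shape != (n_electrodes - 1,):
        raise ValueError("need one delay multiplier per inter-electrode segment")

    if stim_times is None:
        stim_times = np.arange(beats) * cl_ms
    stim_times = np.asarray(stim_times, float)
    seg_delay = spacing_mm / (true_cv / 100.0)  # ms per segment at nominal CV
    offsets = np.concatenate([[0.0], np.cumsum(mult * seg_delay)])
    positions = np.arange(n_electrodes) * spacing_mm

    t_total = stim_times[-1] + offsets[-1] + latency_ms + 50.0
    n = int(round(t_total * sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sampling_rate
    traces = np.zeros((n, n_electrodes))

    truth_times = np.full((len(stim_times), n_electrodes), np.nan)
    propagated = np.ones(len(stim_times), bool)
    last_prop = -np.inf
    for b, ts in enumerate(stim_times):
        if refractory_cutoff_ms is not None and ts - last_prop < refractory_cutoff_ms:
            propagated[b] = False
            continue
        last_prop = ts
        for e in range(n_electrodes):
            center = ts + latency_ms + offsets[e]
            if jitter_sd_ms > 0:
                center += rng.normal(0.0, jitter_sd_ms)
            truth_times[b, e] = center
            traces[:, e] += _biphasic_template(t, center, template_width_ms, amp_mv)
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, traces.shape)

    truth = {
        "true_cv": true_cv,
        "activation_times_ms": truth_times.tolist(),
        "propagated": propagated.tolist(),
        "segment_delay_ms": (mult * seg_delay).tolist(),
    }
    return MEARecording(sampling_rate, positions, traces, stim_times, truth)
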