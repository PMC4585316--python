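"""Discrete resistor-network propagation across a strand architecture.

Every node of the architecture grid carries full LR1 membrane dynamics;
four-neighbor edges carry ohmic conductances: a fixed myoplasmic
conductance inside a cell and ``g_ref x relative coupling factor`` where
the edge crosses a cell boundary (gap junction).  Boundaries are no-flux.
Heterocellular coupling factors follow the minimum-of-pair rule by default
(a junction needs one hemichannel from each cell, so the lower expressor
limits the net conductance).

Numerics: operator splitting with an explicit membrane step (Rush-Larsen
gates, forward Euler V/[Ca]i, dt = 0.005 ms default) and implicit
backward-Euler coupling integrated as two tridiagonal solves per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _propagate as kern
from ._lr1core import build_rl_tables
from .architecture import StrandArchitecture, StrandGeometry, generate_architecture
from .lr1 import CELL_TYPE_INDEX, DEFAULT_CELL_TYPES, CellTypeParams, resting_state

__all__ = [
    "CouplingScheme",
    "PacingProtocol",
    "Network",
    "PropagationResult",
    "ERPResult",
    "build_network",
    "simulate_propagation",
    "calibrate_reference_coupling",
    "run_ramp_protocol",
    "INTRA_G_DEFAULT",
]

# Myoplasmic conductance of one 5-um node-to-node edge, uS.  This is the
# in-plane sheet conductance (sigma x thickness) of the thin cultured
# monolayer; 0.57 uS corresponds to ~1-2 um effective cell thickness at
# 150-300 ohm cm cytoplasmic resistivity.  The value was fixed together with
# the reference junctional conductance against the two coupling anchors of
# the control experiments: all-PCM strands conduct at 34.9 cm/s at relative
# coupling 1, and pure LE-SCM strands at ~5.6 cm/s at relative coupling
# 0.0385.  Junctions still dominate axial resistance (~80% at calibration).
INTRA_G_DEFAULT = 0.57

# Baseline relative coupling levels (diagonal; heterocellular entries follow
# from the minimum-of-pair rule): PCM 1, LE-SCM 0.0385, HE-SCM 0.0205.
_BASELINE_DIAG = (1.0, 0.0385, 0.0205)
# Enhanced heterocellular coupling: PCM-SCM entries increased fourfold and
# LE-HE coupling raised to the LE level.
_ENHANCED_MATRIX = np.array(
    [
        [1.0, 0.1538, 0.0821],
        [0.1538, 0.0385, 0.0385],
        [0.0821, 0.0385, 0.0205],
    ]
)


@dataclass(frozen=True)
class CouplingScheme:
    """Relative junctional coupling per cell-type pair plus the reference
    conductance ``g_ref`` (uS per node-interface) corresponding to 1.0."""

    relative_matrix: np.ndarray
    g_ref: float = 1.0
    rule: str = "explicit"

    def __post_init__(self):
        m = np.asarray(self.relative_matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("relative_matrix must be 3x3")
        if not np.allclose(m, m.T):
            raise ValueError("relative_matrix must be symmetric")
        if np.any(m <= 0) or np.any(m > 1):
            raise ValueError("coupling factors must lie in (0, 1]")
        if self.rule == "min_of_pair":
            expected = np.minimum.outer(np.diag(m), np.diag(m))
            if not np.allclose(m, expected):
                raise ValueError("matrix inconsistent with min_of_pair rule")
        object.__setattr__(self, "relative_matrix", m)

    @classmethod
    def from_diagonal(cls, levels, g_ref: float = 1.0) -> "CouplingScheme":
        levels = np.asarray(levels, dtype=float)
        return cls(np.minimum.outer(levels, levels), g_ref, rule="min_of_pair")

    @classmethod
    def baseline(cls, g_ref: float = 1.0) -> "CouplingScheme":
        return cls.from_diagonal(_BASELINE_DIAG, g_ref)

    @classmethod
    def enhanced(cls, g_ref: float = 1.0) -> "CouplingScheme":
        return cls(_ENHANCED_MATRIX.copy(), g_ref, rule="explicit")

    def with_g_ref(self, g_ref: float) -> "CouplingScheme":
        return replace(self, g_ref=g_ref)


@dataclass(frozen=True)
class PacingProtocol:
    """Stimulation protocol applied to the leftmost ``stim_zone_um``.

    ``steady`` mode paces ``n_beats`` at ``cl_start`` and analyzes the last
    beat; ``ramp`` mode decreases the cycle length beat-to-beat from
    ``cl_start`` to ``cl_end`` at ``ramp_rate`` ms per minute of pacing.
    """

    mode: str = "steady"
    cl_start: float = 300.0
    cl_end: float = 50.0
    ramp_rate: float = 50.0  # ms of CL decrease per minute, ramp mode
    n_beats: int = 1
    stim_amplitude: float = 100.0  # uA/cm2
    stim_duration: float = 2.0  # ms
    stim_zone_um: float = 100.0
    t_max: float = 150.0  # per-beat simulation cap, ms

    def __post_init__(self):
        if self.mode not in ("steady", "ramp"):
            raise ValueError("mode must be 'steady' or 'ramp'")
        if self.cl_start < self.cl_end:
            raise ValueError("cl_start must be >= cl_end")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")

    def ramp_schedule(self) -> np.ndarray:
        """Stimulus times of the descending-CL ramp (ms)."""
        times = [0.0]
        cl = self.cl_start
        while cl >= self.cl_end:
            times.append(times[-1] + cl)
            cl -= self.ramp_rate * cl / 60000.0
        return np.asarray(times)


@dataclass
class Network:
    """Conductance graph over the architecture's node grid."""

    arch: StrandArchitecture
    scheme: CouplingScheme
    intra_g: float
    ctype: np.ndarray  # (ny, nx) uint8
    gx: np.ndarray  # (ny, nx-1) uS, edges along x
    gy: np.ndarray  # (ny-1, nx) uS, edges along y

    @property
    def geometry(self) -> StrandGeometry:
        return self.arch.geometry


def build_network(
    arch: StrandArchitecture,
    scheme: CouplingScheme,
    intra_g: float = INTRA_G_DEFAULT,
) -> Network:
    """Assign an edge conductance to every four-neighbor node pair.

    Edges within a cell get ``intra_g``; edges crossing a cell boundary get
    ``g_ref x relative_matrix[type_a, type_b]``.
    """
    ids = arch.cell_id_grid
    ctype = arch.type_index_grid()
    m = scheme.relative_matrix * scheme.g_ref

    same_x = ids[:, 1:] == ids[:, :-1]
    gx = np.where(same_x, intra_g, m[ctype[:, 1:], ctype[:, :-1]])
    same_y = ids[1:, :] == ids[:-1, :]
    gy = np.where(same_y, intra_g, m[ctype[1:, :], ctype[:-1, :]])
    return Network(arch, scheme, intra_g, ctype, gx.astype(float), gy.astype(float))


@dataclass
class PropagationResult:
    """Activation map of the analyzed beat."""

    eat: np.ndarray  # (ny, nx) ms, NaN where never activated
    dvdtmax: np.ndarray  # (ny, nx) V/s
    activated: np.ndarray  # (ny, nx) bool
    blocked: bool
    aborted: bool
    geometry: StrandGeometry
    dt: float
    steps_run: int
    seed: int | None = None
    beat_success: np.ndarray | None = None
    v_history: np.ndarray | None = None  # decimated (n_snaps, ny, nx), mV
    v_history_dt: float | None = None  # ms between snapshots

    def save_csv(self, eat_path, dvdt_path) -> None:
        np.savetxt(eat_path, self.eat, fmt="%.4f", delimiter=",")
        np.savetxt(dvdt_path, self.dvdtmax, fmt="%.3f", delimiter=",")


def _coupling_coeff(g_us: np.ndarray, node_spacing_um: float) -> np.ndarray:
    """Edge conductance (uS) -> voltage relaxation rate (1/ms).

    c = g / (Cm * A_node) with Cm = 1 uF/cm2 and A = h^2; works out to
    g * 1e5 / h_um^2 per ms.
    """
    return g_us * 1.0e5 / node_spacing_um**2


def _diffusion_prefactors(network: Network, dt: float):
    h = network.geometry.node_spacing
    cx = _coupling_coeff(network.gx, h) * dt  # (ny, nx-1)
    cy = _coupling_coeff(network.gy, h) * dt  # (ny-1, nx)
    ny, nx = network.ctype.shape

    def factor_rows(c, n):
        # c: (n_rows, n-1) scaled edge weights; returns per-row Thomas factors
        n_rows = c.shape[0]
        sub = np.zeros((n_rows, n))
        sup = np.zeros((n_rows, n))
        diag = np.ones((n_rows, n))
        sub[:, 1:] = -c
        sup[:, :-1] = -c
        diag[:, 1:] += c
        diag[:, :-1] += c
        mfac = np.empty((n_rows, n))
        beta = np.empty((n_rows, n))
        for r in range(n_rows):
            mfac[r], beta[r] = kern.thomas_prefactor(sub[r], diag[r], sup[r])
        return mfac, beta, sup

    mx, bx, sx = factor_rows(cx, nx)  # per row (ny rows)
    my, by, sy = factor_rows(cy.T.copy(), ny)  # per column (nx columns)
    return mx, bx, sx, my, by, sy


def _initial_fields(network: Network, dt: float):
    rest = resting_state()
    ny, nx = network.ctype.shape

    def full(v):
        return np.full((ny, nx), v, dtype=np.float64)

    return (
        full(rest.v), full(rest.m), full(rest.h), full(rest.j),
        full(rest.d), full(rest.f), full(rest.x), full(rest.cai),
    )


def _param_arrays(cell_params: dict[str, CellTypeParams]):
    order = sorted(CELL_TYPE_INDEX, key=CELL_TYPE_INDEX.get)
    gna = np.array([cell_params[n].gna_max for n in order])
    gsi = np.array([cell_params[n].gsi_scale for n in order])
    gk = np.array([cell_params[n].gk_scale for n in order])
    tau_d = [cell_params[n].tau_d_scale for n in order]
    tau_f = [cell_params[n].tau_f_scale for n in order]
    return gna, gsi, gk, tau_d, tau_f


def simulate_propagation(
    network: Network,
    cell_params: dict[str, CellTypeParams] | None = None,
    protocol: PacingProtocol | None = None,
    seed: int = 0,
    dt: float = 0.005,
    act_thresh: float = 10.0,
    record_v_every_ms: float | None = None,
) -> PropagationResult:
    """Run a steady-pacing simulation and return the activation map.

    The analyzed beat is the last of ``protocol.n_beats``; earlier beats
    condition the state at ``cl_start``.  The beat ends early once every
    column up to 92% of strand length contains an activated node (plus a
    1-ms margin); the strand counts as blocked when no node in the distal
    10% exceeds ``act_thresh`` (V/s) within the beat window.  With
    ``record_v_every_ms`` set, decimated voltage-field snapshots of the
    analyzed beat are kept in ``v_history``.

    Numerical instability (non-finite or |V| > 200 mV) raises RuntimeError.
    """
    cell_params = cell_params or DEFAULT_CELL_TYPES
    protocol = protocol or PacingProtocol()
    gna, gsi, gk, tau_d, tau_f = _param_arrays(cell_params)
    tables = build_rl_tables(dt, tau_d, tau_f)
    pre = _diffusion_prefactors(network, dt)
    fields = _initial_fields(network, dt)
    ny, nx = network.ctype.shape
    h = network.geometry.node_spacing
    stim_cols = max(1, int(round(protocol.stim_zone_um / h)))

    if protocol.n_beats > 1:
        stim_times = np.arange(protocol.n_beats - 1) * protocol.cl_start
        n_steps = int(round((protocol.n_beats - 1) * protocol.cl_start / dt))
        kern.integrate_paced(
            *fields, network.ctype, tables, gna, gsi, gk, *pre,
            stim_cols, protocol.stim_amplitude, protocol.stim_duration,
            stim_times.astype(np.float64), dt, n_steps,
        )

    eat = np.full((ny, nx), -1.0)
    dvdtmax = np.zeros((ny, nx))
    t_beat = min(protocol.t_max, protocol.cl_start)
    n_steps = int(round(t_beat / dt))
    sentinel_col = min(nx - 1, int(0.92 * nx))
    if record_v_every_ms:
        snap_every = max(1, int(round(record_v_every_ms / dt)))
        snaps = np.empty((n_steps // snap_every + 1, ny, nx))
    else:
        snap_every = 0
        snaps = np.empty((0, ny, nx))
    steps_run, aborted = kern.propagate_beat(
        *fields, network.ctype, tables, gna, gsi, gk, *pre,
        stim_cols, protocol.stim_amplitude, protocol.stim_duration,
        dt, n_steps, act_thresh, sentinel_col,
        max(1, int(round(0.5 / dt))), int(round(1.0 / dt)),
        eat, dvdtmax, snap_every, snaps,
    )
    if aborted:
        raise RuntimeError(
            "numerical instability: |V| > 200 mV or non-finite voltage"
        )
    activated = dvdtmax > act_thresh
    eat = np.where(activated, eat, np.nan)
    distal = activated[:, int(0.9 * nx):]
    blocked = not bool(distal.any())
    v_history = v_dt = None
    if snap_every:
        v_history = snaps[: steps_run // snap_every + 1]
        v_dt = snap_every * dt
    return PropagationResult(
        eat, dvdtmax, activated, blocked, aborted,
        network.geometry, dt, steps_run, seed=seed,
        v_history=v_history, v_history_dt=v_dt,
    )


def calibrate_reference_coupling(
    target_cv: float = 34.9,
    arch_factory=None,
    tolerance: float = 0.15,
    scheme: CouplingScheme | None = None,
    cell_params: dict[str, CellTypeParams] | None = None,
    seeds=(0, 1),
    g_bracket: tuple[float, float] = (0.005, 0.4),
    intra_g: float = INTRA_G_DEFAULT,
    dt: float = 0.005,
    max_iter: int = 40,
) -> tuple[float, float]:
    """Bisect ``g_ref`` until the mean CV of all-PCM strands hits the target.

    ``arch_factory(seed)`` must return a :class:`StrandArchitecture`
    (all-PCM by default).  CV is measured by the 25-75% regression of the
    earliest activation time.  Returns (g_ref, achieved_cv); raises
    RuntimeError when the bracket does not span the target.
    """
    from .analysis import cv_from_activation_map

    if arch_factory is None:
        arch_factory = lambda s: generate_architecture(seed=s)  # noqa: E731
    scheme = scheme or CouplingScheme.baseline()
    archs = [arch_factory(s) for s in seeds]

    def mean_cv(g_ref: float) -> float:
        cvs = []
        for arch in archs:
            net = build_network(arch, scheme.with_g_ref(g_ref), intra_g)
            res = simulate_propagation(net, cell_params, dt=dt)
            est = cv_from_activation_map(res.eat, arch.geometry)
            if est.cv is None:
                # In all-PCM strands a failed wave at this stage means the
                # stimulated zone could not ignite against the electrotonic
                # load, i.e. coupling is too strong, not too weak.
                return float("inf")
            cvs.append(est.cv)
        return float(np.mean(cvs))

    lo, hi = g_bracket
    cv_lo, cv_hi = mean_cv(lo), mean_cv(hi)
    if not (cv_lo < target_cv < cv_hi):
        raise RuntimeError(
            f"target CV {target_cv} outside bracket CVs [{cv_lo:.2f}, {cv_hi:.2f}]"
        )
    cv_mid = cv_lo
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        cv_mid = mean_cv(mid)
        if abs(cv_mid - target_cv) <= tolerance:
            return mid, cv_mid
        if cv_mid < target_cv:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration failed: bracket exhausted at CV {cv_mid:.2f} cm/s"
    )


@dataclass
class ERPResult:
    """Outcome of the descending cycle-length ramp."""

    erp_ms: float | None
    failed_beat: int | None
    censored: bool  # True when no failure occurred down to cl_end
    cl_at_failure: float | None = None

    def __str__(self):
        if self.censored:
            return "ERP <= ramp floor (no failure observed)"
        return f"ERP = {self.erp_ms:.1f} ms (first failure at beat {self.failed_beat})"


def run_ramp_protocol(
    network: Network,
    cell_params: dict[str, CellTypeParams] | None = None,
    protocol: PacingProtocol | None = None,
    dt: float = 0.005,
    act_thresh: float = 30.0,
) -> ERPResult:
    """Descending-CL pacing; ERP is the interval between the last two
    propagated beats immediately before the first distal failure.

    ``act_thresh`` (V/s) discriminates regenerative distal upstrokes
    (hundreds of V/s here) from the small graded responses (~10 V/s) that
    premature stimuli evoke during the relative refractory period; it is
    deliberately stricter than the steady-protocol block criterion."""
    cell_params = cell_params or DEFAULT_CELL_TYPES
    protocol = protocol or PacingProtocol(mode="ramp")
    if protocol.mode != "ramp":
        raise ValueError("ramp protocol required")
    gna, gsi, gk, tau_d, tau_f = _param_arrays(cell_params)
    tables = build_rl_tables(dt, tau_d, tau_f)
    pre = _diffusion_prefactors(network, dt)
    fields = _initial_fields(network, dt)
    ny, nx = network.ctype.shape
    h = network.geometry.node_spacing
    stim_cols = max(1, int(round(protocol.stim_zone_um / h)))
    stim_times = protocol.ramp_schedule()
    distal_col0 = int(0.9 * nx)

    success = kern.run_ramp(
        *fields, network.ctype, tables, gna, gsi, gk, *pre,
        stim_cols, protocol.stim_amplitude, protocol.stim_duration,
        stim_times, dt, act_thresh, distal_col0,
    )
    failures = np.nonzero(success == 0)[0]
    if failures.size == 0:
        return ERPResult(None, None, censored=True)
    k = int(failures[0])
    if k >= 2:
        erp = float(stim_times[k - 1] - stim_times[k - 2])
    else:
        erp = float(stim_times[1] - stim_times[0])
    cl_fail = float(stim_times[k] - stim_times[k - 1]) if k >= 1 else None
    return ERPResult(erp, k, censored=False, cl_at_failure=cl_fail)


def diffusion_step(network: Network, field: np.ndarray, dt: float) -> np.ndarray:
    """Apply one implicit coupling step to an arbitrary field (testing aid)."""
    pre = _diffusion_prefactors(network, dt)
    out = np.array(field, dtype=np.float64)
    ny, nx = out.shape
    kern.diffusion_sweep(out, *pre, np.empty(nx), np.empty(2 * ny))
    return out
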