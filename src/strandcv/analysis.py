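"""Conduction metrics from propagation results.

CV is estimated exactly as in the activation-map protocol: per x-column the
earliest activation time across the strand width is taken, and the
conduction velocity is the inverse slope of the ordinary least-squares
regression of activation time on x restricted to 25-75% of strand length,
which excludes stimulation and boundary artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import StrandGeometry

__all__ = ["CVEstimate", "cv_from_activation_map", "dvdtmax_map", "ols_line"]


def ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares line y = slope*x + intercept.

    Returns (slope, intercept, slope_se, r2).  Shared regression core of the
    activation-map CV and the electrode-array per-beat CV.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate abscissa")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    dof = max(1, len(x) - 2)
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return slope, intercept, slope_se, r2


@dataclass
class CVEstimate:
    """Conduction velocity from the EAT-vs-x regression.

    ``cv`` is None when too few activated columns fall inside the fit
    window.  The slope is in ms/um; cv = 0.1/slope cm/s.
    """

    cv: float | None  # cm/s
    slope: float | None  # ms/um
    slope_se: float | None
    r2: float | None
    n_points: int
    window: tuple[float, float] = (0.25, 0.75)

    @property
    def ok(self) -> bool:
        return self.cv is not None


def cv_from_activation_map(
    eat: np.ndarray,
    geometry: StrandGeometry,
    window: tuple[float, float] = (0.25, 0.75),
    min_points: int = 10,
) -> CVEstimate:
    """OLS of earliest activation time vs x inside the fit window.

    ``eat`` is the (ny, nx) activation-time map in ms with NaN at
    unactivated nodes.  Columns with no activated node are skipped; fewer
    than ``min_points`` usable columns yields a no-estimate result.
    """
    if not 0.0 <= window[0] < window[1] <= 1.0:
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    nx = eat.shape[1]
    h = geometry.node_spacing
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_eat = np.nanmin(eat, axis=0)  # earliest across the width
    x_um = np.arange(nx) * h
    lo, hi = window[0] * geometry.length, window[1] * geometry.length
    sel = (x_um >= lo) & (x_um <= hi) & np.isfinite(col_eat)
    n = int(sel.sum())
    if n < min_points:
        return CVEstimate(None, None, None, None, n, window)
    x = x_um[sel]
    t = col_eat[sel]
    slope, _, slope_se, r2 = ols_line(x, t)
    if slope <= 0:
        return CVEstimate(None, slope, slope_se, r2, n, window)
    cv = 0.1 / slope  # ms/um -> cm/s
    return CVEstimate(cv, slope, slope_se, r2, n, window)


def dvdtmax_map(result) -> np.ndarray:
    """Per-node maximal upstroke rate (V/s) with NaN at unactivated nodes."""
    out = np.array(result.dvdtmax, dtype=float)
    out[~result.activated] = np.nan
    return out
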