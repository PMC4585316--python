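"""Least-squares models of conduction velocity vs SCM proportion.

CV(p) is fitted with a linear (a1 p + a0) and a quadratic
(a2 p^2 + a1 p + a0) polynomial by ordinary least squares.  The
relationship counts as non-linear when zero lies outside the 95%
confidence interval of the quadratic coefficient a2 (classical OLS
t-intervals with n - k degrees of freedom).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["ProportionFit", "fit_cv_vs_proportion", "nonlinearity_verdict"]

NONLINEAR = "nonlinear"
LINEAR_SUFFICIENT = "linear-sufficient"


@dataclass(frozen=True)
class ProportionFit:
    """Polynomial fit of CV (cm/s) against p_SCM with 95% CIs."""

    degree: int
    a0: float
    a1: float
    a2: float | None
    ci95: dict[str, tuple[float, float]]
    n: int
    verdict: str | None  # nonlinear / linear-sufficient; None for linear fits

    def coefficients(self) -> dict[str, float]:
        out = {"a0": self.a0, "a1": self.a1}
        if self.degree == 2:
            out["a2"] = self.a2
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "degree": self.degree,
                "coefficients": self.coefficients(),
                "ci95": {k: list(v) for k, v in self.ci95.items()},
                "n": self.n,
                "verdict": self.verdict,
            },
            indent=1,
        )


def fit_cv_vs_proportion(points, degree: int = 2) -> ProportionFit:
    """OLS polynomial fit of (p_SCM, CV) points.

    ``points`` is an iterable of (p, cv) pairs or an (n, 2) array.  At least
    ``degree + 2`` points with non-identical p values are required so that
    the residual degrees of freedom are positive.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (p, cv) pairs")
    p, cv = arr[:, 0], arr[:, 1]
    n = len(p)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if np.ptp(p) == 0:
        raise ValueError("all p values identical: rank-deficient design")

    cols = [np.ones_like(p), p] + ([p**2] if degree == 2 else [])
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    model = sm.OLS(cv, design).fit()
    ci = model.conf_int(alpha=0.05)
    names = ["a0", "a1", "a2"][: degree + 1]
    ci95 = {nm: (float(ci[k][0]), float(ci[k][1])) for k, nm in enumerate(names)}
    coef = model.params
    a2 = float(coef[2]) if degree == 2 else None
    verdict = None
    if degree == 2:
        lo, hi = ci95["a2"]
        verdict = NONLINEAR if (lo > 0 or hi < 0) else LINEAR_SUFFICIENT
    return ProportionFit(
        degree, float(coef[0]), float(coef[1]), a2, ci95, n, verdict
    )


def nonlinearity_verdict(fit: ProportionFit) -> str:
    """Non-linear iff zero is excluded from the 95% CI of a2."""
    if fit.degree != 2 or fit.a2 is None:
        raise ValueError("nonlinearity verdict requires a quadratic fit")
    lo, hi = fit.ci95["a2"]
    return NONLINEAR if (lo > 0 or hi < 0) else LINEAR_SUFFICIENT
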