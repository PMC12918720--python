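"""Calibration of fitted peak parameters against label number.

With N target docking strands per spot, the fitted peak center grows
linearly in N (the intercept is the background readout level) and, when
per-fluorophore brightness variation dominates, the peak width grows as
sqrt(N) because independent per-strand brightness variances add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "WidthScaling",
    "fit_linear_calibration",
    "fit_width_scaling",
    "predict_count",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """Fitted histogram peak for a sample with N docking strands."""

    N: int
    xc: float
    xc_se: float = math.nan
    fwhm: float = math.nan
    fwhm_se: float = math.nan

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass
class CalibrationCurve:
    """xc = slope * N + intercept, from ordinary least squares."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n_points: int


def _check_distinct(points: Sequence[CalibrationPoint]) -> None:
    if len({p.N for p in points}) < 2:
        raise ValueError("need at least 2 distinct N values")


def fit_linear_calibration(
    points: Sequence[CalibrationPoint],
    weighted: bool = False,
) -> CalibrationCurve:
    """OLS of peak center on strand number.

    The intercept estimates the background intensity readout.  With
    ``weighted=True``, points are weighted by 1/xc_se^2 (all SEs must be
    finite and positive); the default is unweighted.
    """
    _check_distinct(points)
    n = np.array([p.N for p in points], dtype=float)
    xc = np.array([p.xc for p in points], dtype=float)
    if not weighted:
        res = stats.linregress(n, xc)
        return CalibrationCurve(
            slope=float(res.slope), intercept=float(res.intercept),
            slope_se=float(res.stderr), intercept_se=float(res.intercept_stderr),
            r_squared=float(res.rvalue ** 2), n_points=len(points),
        )
    se = np.array([p.xc_se for p in points], dtype=float)
    if not np.isfinite(se).all() or (se <= 0).any():
        raise ValueError("weighted calibration requires finite positive xc SEs")
    w = 1.0 / se ** 2
    X = np.stack([n, np.ones_like(n)], axis=1)
    W = np.diag(w)
    cov = np.linalg.inv(X.T @ W @ X)
    beta = cov @ X.T @ W @ xc
    resid = xc - X @ beta
    # scale covariance by reduced chi-square (errors-in-y regression)
    dof = max(len(points) - 2, 1)
    scale = float(resid @ W @ resid) / dof
    cov = cov * scale
    ybar = np.average(xc, weights=w)
    ss_tot = float(np.sum(w * (xc - ybar) ** 2))
    r2 = 1.0 - float(resid @ W @ resid) / ss_tot if ss_tot > 0 else math.nan
    return CalibrationCurve(
        slope=float(beta[0]), intercept=float(beta[1]),
        slope_se=float(math.sqrt(cov[0, 0])),
        intercept_se=float(math.sqrt(cov[1, 1])),
        r_squared=r2, n_points=len(points),
    )


@dataclass
class WidthScaling:
    """fwhm(N) = coefficient * sqrt(N); optionally with an additive offset."""

    coefficient: float
    coefficient_se: float
    with_offset: bool
    offset: float = 0.0
    offset_se: float = math.nan


def fit_width_scaling(
    points: Sequence[CalibrationPoint],
    with_offset: bool = False,
) -> WidthScaling:
    """Least-squares square-root law for peak width vs strand number.

    The default model is the pure square root fwhm = a * sqrt(N) (closed
    form: a = sum(sqrt(N) * fwhm) / sum(N)); the additive-offset variant
    fwhm = a * sqrt(N) + b is reported with ``with_offset=True`` flagged
    in the result.
    """
    _check_distinct(points)
    n = np.array([p.N for p in points], dtype=float)
    w = np.array([p.fwhm for p in points], dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("all points need finite fwhm values")
    s = np.sqrt(n)
    if not with_offset:
        a = float(np.sum(s * w) / np.sum(n))
        resid = w - a * s
        dof = max(len(points) - 1, 1)
        se = math.sqrt(float(resid @ resid) / dof / float(np.sum(n)))
        return WidthScaling(a, se, with_offset=False)
    res = stats.linregress(s, w)
    return WidthScaling(
        coefficient=float(res.slope), coefficient_se=float(res.stderr),
        with_offset=True, offset=float(res.intercept),
        offset_se=float(res.intercept_stderr),
    )


def predict_count(intensity, curve: CalibrationCurve):
    """Invert the calibration line: count = (intensity - intercept) / slope.

    Negative estimates are clipped to 0 and flagged.  Returns
    ``(counts, clipped)`` arrays (scalars in, scalars out).
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    arr = np.asarray(intensity, dtype=float)
    raw = (arr - curve.intercept) / curve.slope
    clipped = raw < 0
    counts = np.where(clipped, 0.0, raw)
    if arr.ndim == 0:
        return float(counts), bool(clipped)
    return counts, clipped
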