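"""Flexible calibration curves and the rescaled Estimated Calibration Index.

Calibration is assessed one category at a time (one-vs-rest): a local-linear
(loess-type) smooth of the 0/1 event indicator on the predicted probability,
evaluated on a fixed grid over the observed prediction range and clipped to
[0, 1]. Center-specific curves are averaged pointwise with weights equal to
the square root of the center sample size.

The rescaled ECI summarizes a curve in one number:

    ECI = mean_i (p_i - c(p_i))^2  /  mean_i (p_i - ybar)^2

where c is the calibration curve and ybar the observed event rate. It is 0
when the curve coincides with the diagonal (perfect calibration) and 1 when
the curve is horizontal at the event rate (no predictive ability); values
above 1 indicate calibration worse than the horizontal line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import OUTCOME_LEVELS, outcome_codes

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.75
GRID_SIZE = 101
MIN_CURVE_N = 20


@dataclass
class CalibrationCurve:
    """Smoothed predicted-probability -> observed-event-rate mapping."""

    category: str
    grid: np.ndarray
    observed: np.ndarray
    center_id: str = "pooled"
    n: int = 0
    span: float = DEFAULT_SPAN
    degree: int = 1  # local-linear smoother

    @property
    def weight(self) -> float:
        """Meta-analytic weight of a center-specific curve: sqrt(n_c)."""
        return float(np.sqrt(self.n))

    def evaluate(self, predicted) -> np.ndarray:
        """Curve value at arbitrary predictions (boundary extrapolation)."""
        return np.interp(np.asarray(predicted, float), self.grid, self.observed)


def fit_flexible_curve(predicted, events, span: float = DEFAULT_SPAN,
                       grid_size: int = GRID_SIZE, category: str = "",
                       center_id: str = "pooled") -> CalibrationCurve:
    """Local-linear smooth of 0/1 events on predicted probabilities.

    Evaluated on a ``grid_size``-point grid over the observed prediction
    range and clipped to [0, 1]. Raises for fewer than 20 observations or
    all-constant predictions (the smoother would be degenerate).
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(events, dtype=float)
    if p.size != y.size:
        raise ValueError("predicted and events are not aligned")
    if p.size < MIN_CURVE_N:
        raise ValueError(f"need >= {MIN_CURVE_N} observations for a calibration curve")
    if np.ptp(p) == 0.0:
        raise ValueError(
            "all predictions identical: calibration curve is degenerate "
            "(horizontal by construction)"
        )
    grid = np.linspace(p.min(), p.max(), grid_size)
    smooth = lowess(y, p, frac=span, it=0, xvals=grid)
    return CalibrationCurve(category, grid, np.clip(smooth, 0.0, 1.0),
                            center_id=center_id, n=p.size, span=span)


def average_center_curves(curves: list[CalibrationCurve],
                          grid_size: int = GRID_SIZE) -> CalibrationCurve:
    """Pointwise sqrt(n)-weighted average of center-specific curves.

    Curves are re-interpolated onto a common grid; a grid point is kept only
    where at least two centers' observed prediction ranges cover it (a
    single curve is returned unchanged).
    """
    if not curves:
        raise ValueError("no curves to average")
    cats = {c.category for c in curves}
    if len(cats) > 1:
        raise ValueError(f"cannot average curves of different categories: {cats}")
    if len(curves) == 1:
        return curves[0]
    lo = min(c.grid[0] for c in curves)
    hi = max(c.grid[-1] for c in curves)
    grid = np.linspace(lo, hi, grid_size)
    vals = np.full((len(curves), grid_size), np.nan)
    w = np.array([c.weight for c in curves])
    for i, c in enumerate(curves):
        inside = (grid >= c.grid[0]) & (grid <= c.grid[-1])
        vals[i, inside] = np.interp(grid[inside], c.grid, c.observed)
    covered = (~np.isnan(vals)).sum(axis=0) >= 2
    if not covered.any():
        raise ValueError("no grid point is covered by at least two centers")
    grid = grid[covered]
    vals = vals[:, covered]
    mask = ~np.isnan(vals)
    wmat = np.where(mask, w[:, None], 0.0)
    avg = np.nansum(np.where(mask, vals, 0.0) * wmat, axis=0) / wmat.sum(axis=0)
    n_total = int(sum(c.n for c in curves))
    return CalibrationCurve(curves[0].category, grid, avg, center_id="pooled",
                            n=n_total, span=curves[0].span)


def rescaled_eci(predicted, events, curve: CalibrationCurve) -> float:
    """Rescaled Estimated Calibration Index against a fitted curve.

    0 for a diagonal curve, 1 for a horizontal curve at the event rate;
    floored at 0, may exceed 1 for worse-than-horizontal calibration.
    Predictions outside the curve's grid use the boundary curve value.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(events, dtype=float)
    c = curve.evaluate(p)
    denom = float(np.mean((p - y.mean()) ** 2))
    if denom == 0.0:
        raise ValueError(
            "rescaled ECI undefined: all predictions equal the event rate"
        )
    raw = float(np.mean((p - c) ** 2))
    return max(raw / denom, 0.0)


@dataclass(frozen=True)
class EciResult:
    per_category_eci: np.ndarray
    mean_eci: float


def multiclass_eci(probabilities, outcomes,
                   pooled_curves: dict[str, CalibrationCurve]) -> EciResult:
    """Per-category (one-vs-rest) rescaled ECI and its unweighted mean."""
    P = np.asarray(probabilities, dtype=float)
    codes = outcome_codes(outcomes)
    per = np.empty(len(OUTCOME_LEVELS))
    for k, level in enumerate(OUTCOME_LEVELS):
        if level not in pooled_curves:
            raise ValueError(f"missing pooled calibration curve for {level!r}")
        per[k] = rescaled_eci(P[:, k], codes == k, pooled_curves[level])
    return EciResult(per, float(per.mean()))


def per_center_curves(probabilities, outcomes, centers, category_index: int,
                      span: float = DEFAULT_SPAN,
                      min_n: int = MIN_CURVE_N) -> list[CalibrationCurve]:
    """Fit one calibration curve per eligible center for one category.

    A center is eligible when it has at least ``min_n`` patients and both
    event and non-event patients for the category; ineligible centers are
    logged and contribute only to pooled evaluation.
    """
    P = np.asarray(probabilities, dtype=float)
    codes = outcome_codes(outcomes)
    centers = np.asarray(centers)
    level = OUTCOME_LEVELS[category_index]
    out = []
    for c in np.unique(centers):
        mask = centers == c
        y = (codes[mask] == category_index).astype(float)
        if mask.sum() < min_n or y.min() == y.max():
            logger.info("center %s excluded from %s calibration curve "
                        "(n=%d, events=%d)", c, level, mask.sum(), int(y.sum()))
            continue
        p = P[mask, category_index]
        if np.ptp(p) == 0.0:
            logger.info("center %s excluded from %s curve (constant predictions)",
                        c, level)
            continue
        out.append(fit_flexible_curve(p, y, span=span, category=level,
                                      center_id=str(c)))
    return out


def pooled_calibration_curves(probabilities, outcomes, centers,
                              span: float = DEFAULT_SPAN) -> dict[str, CalibrationCurve]:
    """Center-averaged flexible curve per category; falls back to a single
    pooled-data curve when fewer than two centers are eligible."""
    P = np.asarray(probabilities, dtype=float)
    codes = outcome_codes(outcomes)
    curves = {}
    for k, level in enumerate(OUTCOME_LEVELS):
        per_center = per_center_curves(P, codes, centers, k, span=span)
        if len(per_center) >= 2:
            curves[level] = average_center_curves(per_center)
        else:
            logger.info("category %s: <2 eligible centers, using pooled-data curve",
                        level)
            curves[level] = fit_flexible_curve(
                P[:, k], (codes == k).astype(float), span=span, category=level)
    return curves
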