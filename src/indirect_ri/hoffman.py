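"""Computerised Hoffman estimation.

The Hoffman method assumes physiological results are Gaussian, plots the
sorted results against standard-normal quantiles (a normal-probability /
cumulative-frequency plot) and fits a straight line to the portion of
the plot judged linear — i.e. dominated by healthy results.  The
reference limits are the line evaluated at z = -/+1.959964.

The classical method identifies the linear portion visually; the
computerised variant here replaces that judgement with a reproducible
segment search: contiguous central quantile windows on a grid, ordinary
least squares per window, and selection of the *widest* window whose
coefficient of determination reaches a threshold (tie-broken by r^2).
If no window reaches the threshold the best-r^2 window is used with a
warning.  All thresholds are configuration, not constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import norm, rankdata

from .boxcox import ReferenceInterval
from .data_io import MeasurementSeries
from .errors import FitError, InsufficientDataError

__all__ = ["HoffmanConfig", "HoffmanFit", "cumulative_plot", "fit_hoffman"]

#: exact standard-normal 97.5% quantile (two-sided 95%)
_Z95 = float(norm.ppf(0.975))

_MIN_N = 40


@dataclass(frozen=True)
class HoffmanConfig:
    """Segment-search settings.

    grid_step : quantile grid for candidate window endpoints
    min_mass : minimum probability mass a window must cover
    bounds : windows are contained in [bounds[0], bounds[1]]
    r2_threshold : linearity acceptance threshold
    log_scale : fit on log-values and exponentiate the limits
        (off by default: classic Hoffman works on the original scale)
    """

    grid_step: float = 0.01
    min_mass: float = 0.40
    bounds: Tuple[float, float] = (0.05, 0.95)
    r2_threshold: float = 0.99
    log_scale: bool = False


@dataclass(frozen=True)
class HoffmanFit:
    slope: float
    intercept: float
    r2: float
    segment: Tuple[float, float]
    ri: ReferenceInterval
    threshold_met: bool = True

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise FitError(f"r2 out of range: {self.r2}")
        if self.slope <= 0:
            raise FitError("Hoffman slope must be positive")


def cumulative_plot(series: MeasurementSeries) -> Tuple[np.ndarray, np.ndarray]:
    """Sorted values paired with standard-normal plotting quantiles.

    The i-th order statistic is assigned probability (i - 0.5)/n (Hazen
    plotting position, which avoids the 0 and 1 endpoints) and mapped
    through the standard-normal quantile function.  Ties — ubiquitous in
    rounded laboratory data — share their mean rank, so a repeated value
    appears at one averaged z rather than a vertical run.

    Returns ``(values, z)``, both ascending in value.
    """
    if series.n < 2:
        raise InsufficientDataError("cumulative plot needs at least 2 values")
    v = np.sort(series.values)
    ranks = rankdata(v, method="average")
    p = (ranks - 0.5) / series.n
    return v, norm.ppf(p)


def fit_hoffman(
    series: MeasurementSeries, config: Optional[HoffmanConfig] = None
) -> HoffmanFit:
    """Fit the computerised Hoffman line and extrapolate the 95% RI.

    Searches contiguous quantile windows [q_lo, q_hi] with endpoints on
    ``config.grid_step``, within ``config.bounds``, covering at least
    ``config.min_mass`` probability; OLS of value on z per window; the
    selected window is the widest with r^2 >= threshold (ties to higher
    r^2), else the best-r^2 window with a warning.  The reference
    interval is the fitted line at z = -/+1.959964.
    """
    cfg = config or HoffmanConfig()
    if series.n < _MIN_N:
        raise InsufficientDataError(
            f"Hoffman fit needs at least {_MIN_N} values, got {series.n}"
        )

    v, z = cumulative_plot(series)
    if cfg.log_scale:
        v = np.log(v)
    p = norm.cdf(z)
    if np.ptp(series.values) == 0:
        raise FitError("constant series: cumulative plot has no spread")

    # prefix sums -> O(1) OLS per window
    def pref(a):
        out = np.zeros(a.size + 1)
        np.cumsum(a, out=out[1:])
        return out

    Sz, Sz2 = pref(z), pref(z * z)
    Sv, Sv2, Szv = pref(v), pref(v * v), pref(z * v)

    lo_q, hi_q = cfg.bounds
    grid = np.round(
        np.arange(lo_q, hi_q + cfg.grid_step / 2, cfg.grid_step), 10
    )
    best = None           # (width, r2, q1, q2, slope, intercept)
    best_any = None       # same, ignoring the threshold
    for i, q1 in enumerate(grid):
        for q2 in grid[i + 1:]:
            if q2 - q1 < cfg.min_mass - 1e-12:
                continue
            a = np.searchsorted(p, q1, side="left")
            b = np.searchsorted(p, q2, side="right")
            m = b - a
            if m < 3:
                continue
            sz, sz2 = Sz[b] - Sz[a], Sz2[b] - Sz2[a]
            sv, sv2, szv = Sv[b] - Sv[a], Sv2[b] - Sv2[a], Szv[b] - Szv[a]
            var_z = sz2 - sz * sz / m
            var_v = sv2 - sv * sv / m
            cov = szv - sz * sv / m
            if var_z <= 0 or var_v <= 0:
                continue
            slope = cov / var_z
            if slope <= 0:
                continue
            r2 = cov * cov / (var_z * var_v)
            cand = (q2 - q1, r2, q1, q2, slope, (sv - slope * sz) / m)
            if best_any is None or r2 > best_any[1]:
                best_any = cand
            if r2 >= cfg.r2_threshold and (best is None or cand[:2] > best[:2]):
                best = cand

    if best is None:
        if best_any is None:
            raise FitError("no candidate window admits a positive-slope fit")
        warnings.warn(
            f"no window reached r2 >= {cfg.r2_threshold}; "
            f"using best window r2={best_any[1]:.5f}",
            stacklevel=2,
        )
        best = best_any
        threshold_met = False
    else:
        threshold_met = True

    width, r2, q1, q2, slope, intercept = best
    lower = intercept - _Z95 * slope
    upper = intercept + _Z95 * slope
    if cfg.log_scale:
        lower, upper = np.exp(lower), np.exp(upper)
    if lower <= 0:
        # Extrapolating a line fitted on the original scale of a skewed
        # analyte can cross zero; clip to half the reporting resolution
        # so the limit stays a representable positive value.
        warnings.warn(
            f"extrapolated lower limit {lower:.4g} <= 0; "
            f"clipped to half the reporting resolution",
            stacklevel=2,
        )
        lower = 0.5 * series.resolution
    ri = ReferenceInterval(lower=float(lower), upper=float(upper), method="hoffman")
    return HoffmanFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=float(min(r2, 1.0)),
        segment=(float(q1), float(q2)),
        ri=ri,
        threshold_met=threshold_met,
    )
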