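"""Inverse-modelling estimation (refineR-style).

Three steps:

1. *Peak and search region* — a histogram at (at least) the reporting
   resolution is smoothed with a 3-bin moving average; the principal
   peak is the tallest smoothed bin and the search region is the widest
   contiguous run around it where smoothed counts stay above 10% of the
   peak height.  The region is where the healthy component dominates.
2. *Multi-level grid search* — the healthy component is a
   Box-Cox-Gaussian scaled by P, the fraction of all results attributed
   to it.  A coarse grid over (lambda, mu, sigma, P) is scored by a
   one-sided penalized chi-square on binned counts (below); each
   subsequent level re-grids +/-1 coarse step around the incumbent at
   5x resolution.
3. *Reference interval* — closed-form percentiles of the lowest-cost
   model; optional percentile-bootstrap confidence intervals for both
   limits (resampling the dataset, refitting, taking quantiles of the
   replicate limits).

Cost function.  Inside the search region the discrepancy between
observed bin counts and P*n*(model bin probability) is an *asymmetric*
Pearson chi-square: model overshoot (expected above observed) carries
full weight, observed excess carries a small weight, because
pathological results only ever add counts on top of the healthy
component.  Outside the region only overshoot is penalized, so distant
pathological mass is free but the healthy model may never exceed what
was observed.  The model median must lie inside the search region,
anchoring the fit to the principal peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import ndtr

from .boxcox import BoxCoxGaussian, ReferenceInterval, boxcox, model_ri
from .data_io import MeasurementSeries
from .errors import CIError, DomainError, FitError

__all__ = [
    "RefineRFit",
    "find_peak_region",
    "fit_refiner",
    "bootstrap_ci",
    "evaluate_cost",
]

_WARN_MIN_N = 500
_P_GRID = np.round(np.arange(0.30, 1.0001, 0.10), 10)
_LAM_GRID = np.round(np.linspace(0.0, 1.0, 11), 10)
_REGION_FRACTION = 0.10
_UPTURN_FACTOR = 1.25   # rise above the running minimum that ends a flank
_COUNT_FLOOR = 0.5   # chi-square denominator floor for near-empty bins
#: weight of observed-excess (O > E) relative to model-overshoot (E > O)
#: inside the region; pathological results add counts, so excess is
#: down-weighted rather than treated as symmetric lack of fit
_EXCESS_WEIGHT = 0.25


@dataclass(frozen=True)
class RefineRFit:
    """Lowest-cost model with its scaling factor and search region."""

    model: BoxCoxGaussian
    p_scale: float
    cost: float
    ri: ReferenceInterval
    search_region: Tuple[float, float]
    peak: float = np.nan

    def __post_init__(self):
        if not 0.0 < self.p_scale <= 1.0:
            raise FitError(f"p_scale must be in (0,1], got {self.p_scale}")
        lo, hi = self.search_region
        if not lo < hi:
            raise FitError("search region must be ordered")


_MAX_BINS = 2500


def _histogram(series: MeasurementSeries):
    """Counts on bins at the reporting resolution.

    Rounded values are bin centers, so the histogram is exact for the
    reported data.  Only when the span would exceed _MAX_BINS bins is
    the width widened (to an integer multiple of the resolution), which
    keeps long contaminated tails from exploding the bin count.
    """
    v = series.values
    res = series.resolution
    span = float(v.max() - v.min()) + res
    width = res * max(1, int(np.ceil(span / res / _MAX_BINS)))
    lo = np.floor(v.min() / res) * res - res / 2
    edges = np.arange(lo, v.max() + width, width)
    counts, edges = np.histogram(v, bins=edges)
    return edges, counts.astype(float)


def _fit_histogram(series: MeasurementSeries, region):
    """Histogram used by the chi-square fit.

    Peak/region *detection* needs resolution-width bins (see
    :func:`_histogram`), but the fit needs stable per-bin counts; the
    fit width puts ~25 bins across the interquartile range of the
    in-region data, floored at the reporting resolution and rounded up
    to an integer multiple of it so rounded values stay at bin
    interiors.  The width depends only on the data's *distribution*,
    so exact duplication of the dataset leaves the fit unchanged.
    """
    v = series.values
    res = series.resolution
    inside = v[(v >= region[0]) & (v <= region[1])]
    iqr = float(np.subtract(*np.percentile(inside, [75, 25]))) if inside.size else 0.0
    width = res * max(1, int(np.ceil(iqr / 25.0 / res))) if iqr > 0 else res
    lo = np.floor(v.min() / res) * res - res / 2
    edges = np.arange(lo, v.max() + width, width)
    counts, edges = np.histogram(v, bins=edges)
    return edges, counts.astype(float)


def _smooth3(counts):
    return np.convolve(counts, np.ones(3) / 3.0, mode="same")


def find_peak_region(
    series: MeasurementSeries,
) -> Tuple[Tuple[float, float], float]:
    """Locate the principal peak and the parameter search region.

    Returns ``((low, high), peak_location)`` in analyte units.  Raises
    :class:`FitError` on degenerate (single-value) data; warns on small
    n and on non-adjacent near-ties for the tallest bin (the leftmost
    tallest bin is then used).
    """
    if series.n < _WARN_MIN_N:
        warnings.warn(f"n={series.n} < {_WARN_MIN_N}: peak location unstable",
                      stacklevel=2)
    if np.unique(series.values).size < 3:
        raise FitError("degenerate data: fewer than 3 distinct values")
    edges, counts = _histogram(series)
    sm = _smooth3(counts)
    top = sm.max()
    tall = np.flatnonzero(sm >= 0.99 * top)
    if tall.size > 1 and np.any(np.diff(tall) > 1):
        warnings.warn("near-tied non-adjacent histogram peaks; using leftmost",
                      stacklevel=2)
    peak_bin = int(tall[0])

    def expand(direction):
        # Walk away from the peak while smoothed counts stay above the
        # height floor; stop early if counts turn back upward after a
        # clear descent — a rising flank signals a secondary
        # (pathological) mode that must stay outside the region.
        i = peak_bin
        run_min = sm[peak_bin]
        while True:
            j = i + direction
            if j < 0 or j >= sm.size:
                break
            if sm[j] <= _REGION_FRACTION * top:
                break
            # the rise must be both relative (25%) and Poisson-significant
            if (
                run_min < 0.5 * top
                and sm[j] > _UPTURN_FACTOR * run_min
                and sm[j] - run_min > 5.0 * np.sqrt(max(run_min, 1.0))
            ):
                break
            run_min = min(run_min, sm[j])
            i = j
        return i

    lo_bin, hi_bin = expand(-1), expand(+1)
    if hi_bin - lo_bin < 2:
        raise FitError("degenerate search region (fewer than 3 bins)")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return (float(edges[lo_bin]), float(edges[hi_bin + 1])), float(centers[peak_bin])


def _bin_probs(edges_t, mu, sigma):
    """Model probability per bin for transformed edges; ``mu``/``sigma``
    may be arrays (grid rows)."""
    z = (edges_t[None, :] - np.atleast_1d(mu)[:, None]) / np.atleast_1d(sigma)[:, None]
    F = ndtr(z)
    return np.diff(F, axis=1)


def _transform_edges(edges, lam):
    out = np.full(edges.shape, -np.inf)
    pos = edges > 0
    out[pos] = boxcox(edges[pos], lam)
    return out


def _cost_matrix(probs, counts, in_region, mu, sigma, lam, region_t, n, p_scale):
    """Cost for every (grid row, P) combination.

    Inside the search region: an asymmetric Pearson chi-square — full
    weight on model overshoot (E > O), weight _EXCESS_WEIGHT on observed
    excess (O > E), because pathological results only ever add counts.
    Outside the region only overshoot is penalized.  Candidates whose
    median (mu, transformed scale) falls outside the search region are
    infeasible (+inf): the model must explain the principal peak, not a
    pathological side mode.

    probs : (G, B) model bin probabilities
    region_t : (lo, hi) search region on the transformed scale
    p_scale : (P,) scaling factors
    returns (P, G) cost array
    """
    expected = p_scale[:, None, None] * n * probs[None, :, :]   # (P, G, B)
    obs = counts[None, None, :]
    denom = np.maximum(expected, _COUNT_FLOOR)
    overshoot = np.square(np.maximum(expected - obs, 0.0)) / denom
    excess = np.square(np.maximum(obs - expected, 0.0)) / denom
    # inside the region: full weight on model overshoot, reduced weight
    # on observed excess (contamination only ever adds counts); outside:
    # overshoot only
    two_sided = overshoot + _EXCESS_WEIGHT * excess
    contrib = np.where(in_region[None, None, :], two_sided, overshoot)
    cost = contrib.sum(axis=2)
    feasible = (mu >= region_t[0]) & (mu <= region_t[1])
    if abs(lam) >= 1e-8:
        # the candidate must have a defined central-95% interval
        z95 = 1.959963984540054
        feasible &= lam * (mu - z95 * sigma) + 1.0 > 0
        feasible &= lam * (mu + z95 * sigma) + 1.0 > 0
    cost[:, ~feasible] = np.inf
    return cost


def _region_transformed(region, lam):
    lo = boxcox(region[0], lam) if region[0] > 0 else -np.inf
    return lo, boxcox(region[1], lam)


def evaluate_cost(
    series: MeasurementSeries,
    model: BoxCoxGaussian,
    p_scale: float,
    region: Optional[Tuple[float, float]] = None,
) -> float:
    """Cost of a given (model, P) against a series — the same objective
    the grid search minimizes, exposed for diagnostics and testing."""
    if region is None:
        region, _ = find_peak_region(series)
    edges, counts = _fit_histogram(series, region)
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_region = (centers >= region[0]) & (centers <= region[1])
    edges_t = _transform_edges(edges, model.lam)
    probs = _bin_probs(edges_t, model.mu, model.sigma)
    cost = _cost_matrix(
        probs, counts, in_region, np.atleast_1d(model.mu),
        np.atleast_1d(model.sigma), model.lam,
        _region_transformed(region, model.lam),
        series.n, np.array([p_scale]),
    )
    return float(cost[0, 0])


def _initial_moments(edges, counts, in_region, lam):
    """Weighted moments of transformed bin centers inside the region."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    c = centers[in_region]
    w = counts[in_region]
    pos = c > 0
    c, w = c[pos], w[pos]
    y = boxcox(c, lam)
    wm = np.average(y, weights=w)
    wv = np.average(np.square(y - wm), weights=w)
    return wm, float(np.sqrt(max(wv, 1e-12)))


def fit_refiner(
    series: MeasurementSeries,
    levels: int = 3,
    boot: Optional[int] = None,
    ci_level: float = 0.95,
    seed: Optional[int] = None,
) -> RefineRFit:
    """Multi-level grid search for the lowest-cost scaled model.

    Level 1 grids lambda over {0, 0.1, ..., 1}, P over {0.3, ..., 1.0},
    and (mu, sigma) around moment estimates of the transformed search
    region (+/-3 spacings of sigma/2 and sigma/4).  Each further level
    re-grids every parameter +/-1 coarse step around the incumbent at
    5x resolution.  Deterministic given the series.  With ``boot`` set,
    percentile-bootstrap CIs at ``ci_level`` are attached to the
    reference interval.
    """
    if levels < 1:
        raise DomainError("levels must be >= 1")
    region, peak = find_peak_region(series)
    edges, counts = _fit_histogram(series, region)
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_region = (centers >= region[0]) & (centers <= region[1])
    n = series.n

    def eval_grid(lam_grid, mu_sigma_grids, p_grid):
        """mu_sigma_grids: lam -> (mu_grid, sigma_grid); full cross product."""
        incumbent = None
        for lam in lam_grid:
            mu_g, sg_g = mu_sigma_grids(lam)
            MU, SG = np.meshgrid(mu_g, sg_g, indexing="ij")
            mu_f, sg_f = MU.ravel(), SG.ravel()
            ok = sg_f > 0
            if not ok.any():
                continue
            mu_f, sg_f = mu_f[ok], sg_f[ok]
            edges_t = _transform_edges(edges, lam)
            probs = _bin_probs(edges_t, mu_f, sg_f)
            cost = _cost_matrix(
                probs, counts, in_region, mu_f, sg_f, lam,
                _region_transformed(region, lam), n, p_grid,
            )
            cost = np.where(np.isfinite(cost), cost, np.inf)
            pi, gi = np.unravel_index(np.argmin(cost), cost.shape)
            c = cost[pi, gi]
            if incumbent is None or c < incumbent[0]:
                incumbent = (float(c), float(lam), float(mu_f[gi]),
                             float(sg_f[gi]), float(p_grid[pi]))
        return incumbent

    # level 1: moment-anchored (mu, sigma) grids per lambda
    def level1_grids(lam):
        m, s = _initial_moments(edges, counts, in_region, lam)
        mu_g = m + np.arange(-3, 4) * (s / 2.0)
        sg_g = s * (1.0 + np.arange(-3, 4) / 4.0)
        return mu_g, sg_g[sg_g > 0]

    incumbent = eval_grid(_LAM_GRID, level1_grids, _P_GRID)
    if incumbent is None or not np.isfinite(incumbent[0]):
        raise FitError("no finite cost on the level-1 grid")

    spacing = {
        "lam": float(np.diff(_LAM_GRID).max()),
        "p": float(np.diff(_P_GRID).max()),
    }
    _, lam0, mu0, sg0, p0 = incumbent
    m1, s1 = _initial_moments(edges, counts, in_region, lam0)
    spacing["mu"] = s1 / 2.0
    spacing["sigma"] = s1 / 4.0

    for _ in range(1, levels):
        for key in spacing:
            spacing[key] /= 5.0
        _, lam0, mu0, sg0, p0 = incumbent
        steps = np.arange(-5, 6)
        lam_g = np.clip(lam0 + steps * spacing["lam"], -0.5, 1.5)
        p_g = np.clip(p0 + steps * spacing["p"], 0.05, 1.0)
        p_g = np.unique(np.round(p_g, 12))
        mu_g = mu0 + steps * spacing["mu"]
        sg_g = sg0 + steps * spacing["sigma"]

        def grids(lam, mu_g=mu_g, sg_g=sg_g):
            return mu_g, sg_g[sg_g > 0]

        cand = eval_grid(np.unique(np.round(lam_g, 12)), grids, p_g)
        if cand is not None and cand[0] < incumbent[0]:
            incumbent = cand

    cost, lam, mu, sigma, p = incumbent
    model = BoxCoxGaussian(lam=lam, mu=mu, sigma=sigma)
    ri = model_ri(model, method="refiner")

    if boot is not None:
        ci_lo, ci_hi, _ = bootstrap_ci(
            series, levels=levels, n_boot=boot, level=ci_level, seed=seed
        )
        ri = ReferenceInterval(
            lower=ri.lower, upper=ri.upper, method="refiner",
            ci_lower=ci_lo, ci_upper=ci_hi, ci_level=ci_level,
        )
    return RefineRFit(
        model=model, p_scale=p, cost=cost, ri=ri,
        search_region=region, peak=peak,
    )


def bootstrap_ci(
    series: MeasurementSeries,
    levels: int = 3,
    n_boot: int = 200,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> Tuple[Tuple[float, float], Tuple[float, float], int]:
    """Percentile-bootstrap CIs for both reference limits.

    ``n_boot`` resamples with replacement of size n, each refit from
    scratch; failed replicates are dropped and counted, with more than
    20% failures raising :class:`CIError`.  Returns
    ``(ci_lower, ci_upper, n_failed)``; reproducible given ``seed``.
    """
    if n_boot < 2:
        raise DomainError("n_boot must be >= 2")
    if not 0 < level < 1:
        raise DomainError("level must be in (0,1)")
    rng = np.random.default_rng(seed)
    lows, highs, failed = [], [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, series.n, series.n)
        resample = MeasurementSeries(
            analyte_name=series.analyte_name,
            unit=series.unit,
            values=series.values[idx],
            decimals=series.decimals,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_refiner(resample, levels=levels)
            lows.append(fit.ri.lower)
            highs.append(fit.ri.upper)
        except (FitError, DomainError):
            failed += 1
    if failed > 0.2 * n_boot:
        raise CIError(f"{failed}/{n_boot} bootstrap replicates failed")
    q = [(1 - level) / 2, (1 + level) / 2]
    lo_pair = tuple(float(x) for x in np.quantile(lows, q))
    hi_pair = tuple(float(x) for x in np.quantile(highs, q))
    return lo_pair, hi_pair, failed
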