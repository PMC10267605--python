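"""Truncation-search estimation (KOSMIC-style).

The healthy component of a mixed hospital distribution is estimated by
(1) Box-Cox transforming the data, (2) fitting a *truncated* Gaussian to
the observations inside a candidate truncation interval, and (3) scoring
the fit by a Kolmogorov-Smirnov distance between the renormalized
empirical CDF of the inside-observations and the truncated-Gaussian CDF.
Candidate truncation intervals are sample-quantile pairs on a grid; the
transform power lambda is searched on a grid and refined locally.  The
candidate with the smallest (penalized) KS distance wins, and the
reference interval is the closed-form 2.5th/97.5th percentile of the
winning Box-Cox-Gaussian model.

The raw KS distance degenerately favours the narrowest truncation (any
model matches few points well), so by default the objective divides the
KS distance by sqrt(fraction of data inside the interval); the
penalization is switchable.

Maximum likelihood for a doubly truncated Gaussian with known bounds is
an exponential family problem: the MLE matches the truncated model's
first two moments to the sample moments of the inside-observations.
The public :func:`truncated_gauss_ml` solves the NLL with scipy; the
grid search uses a vectorized moment-matching fixed point over all
candidate intervals at once, which converges to the same solution (the
two are cross-checked in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr
from scipy.stats import norm
import yaml

from .boxcox import BoxCoxGaussian, ReferenceInterval, boxcox, model_ri
from .data_io import MeasurementSeries
from .errors import (
    ConfigurationError,
    ConvergenceError,
    DomainError,
    FitError,
    InsufficientDataError,
)

__all__ = [
    "KosmicConfig",
    "KosmicFit",
    "truncated_gauss_ml",
    "ks_truncated",
    "fit_kosmic",
]

_HARD_MIN_N = 50
_WARN_MIN_N = 500


@dataclass(frozen=True)
class KosmicConfig:
    """Search settings for the truncation-grid fit.

    t1_min..t2_max : truncation search bounds as sample quantiles
    step : quantile grid step for candidate truncation pairs
    lambda_grid : candidate Box-Cox powers (refined locally afterwards);
        the default 0.05 step plus local refinement resolves lambda to
        ``lambda_xatol`` without scanning a needlessly fine grid
    tolerance : convergence tolerance of the truncated-ML optimizer
    lambda_xatol : absolute tolerance of the local lambda refinement
    penalize : divide KS by sqrt(inside fraction) (see module docstring)
    min_inside : hard floor on observations inside a candidate interval
    sd_param : opaque upstream setting, carried for provenance only —
        it does not enter the computation
    """

    t1_min: float = 0.05
    t1_max: float = 0.30
    t2_min: float = 0.70
    t2_max: float = 0.95
    step: float = 0.01
    lambda_grid: Tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    tolerance: float = 1e-7
    lambda_xatol: float = 1e-3
    penalize: bool = True
    min_inside: int = _HARD_MIN_N
    sd_param: Optional[float] = None

    def __post_init__(self):
        if not 0 < self.t1_min < self.t1_max < self.t2_min < self.t2_max < 1:
            raise ConfigurationError(
                "need 0 < t1_min < t1_max < t2_min < t2_max < 1"
            )
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")
        if len(self.lambda_grid) == 0:
            raise ConfigurationError("lambda_grid must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "KosmicConfig":
        """Load a config whose keys mirror the upstream field names
        (t1min/t1max/t2min/t2max/decimals/tolerance/sd)."""
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        mapping = {
            "t1min": "t1_min", "t1max": "t1_max",
            "t2min": "t2_min", "t2max": "t2_max",
            "tolerance": "tolerance", "sd": "sd_param",
            "step": "step", "penalize": "penalize",
        }
        kwargs = {}
        for key, attr in mapping.items():
            if key in doc:
                kwargs[attr] = doc[key]
        if "lambda_grid" in doc:
            kwargs["lambda_grid"] = tuple(doc["lambda_grid"])
        return cls(**kwargs)


@dataclass(frozen=True)
class KosmicFit:
    """Result of the truncation-search fit."""

    model: BoxCoxGaussian
    t1: float                    # lower truncation value, analyte units
    t2: float                    # upper truncation value, analyte units
    ks: float                    # raw KS distance at the optimum
    ri: ReferenceInterval
    score: float = np.nan        # penalized objective at the optimum
    quantile_window: Tuple[float, float] = (np.nan, np.nan)
    n_inside: int = 0

    def __post_init__(self):
        if not self.t1 < self.t2:
            raise FitError("truncation bounds must be ordered")
        if not 0.0 <= self.ks <= 1.0:
            raise FitError(f"KS distance out of [0,1]: {self.ks}")


def _suffstat_nll(mu, sigma, a, b, m, s1, s2):
    """Truncated-normal negative log-likelihood from sufficient stats
    (count m, sum s1, sum of squares s2) of the inside-observations."""
    alpha = (a - mu) / sigma
    beta = (b - mu) / sigma
    Z = np.clip(ndtr(beta) - ndtr(alpha), 1e-300, None)
    return (
        m * np.log(sigma)
        + (s2 - 2 * mu * s1 + m * mu * mu) / (2 * sigma * sigma)
        + m * np.log(Z)
    )


def truncated_gauss_ml(
    y: Sequence[float],
    t1y: float,
    t2y: float,
    tolerance: float = 1e-7,
    min_inside: int = _HARD_MIN_N,
) -> Tuple[float, float]:
    """ML (mu, sigma) of a Gaussian truncated to [t1y, t2y].

    Only observations inside the interval enter the likelihood; the
    bounds are treated as known.  Raises on fewer than ``min_inside``
    inside-observations, zero inside variance, or non-convergence.
    """
    if not t1y < t2y:
        raise DomainError("truncation bounds must satisfy t1y < t2y")
    y = np.asarray(y, dtype=float)
    inside = y[(y >= t1y) & (y <= t2y)]
    m = inside.size
    if m < min_inside:
        raise InsufficientDataError(
            f"only {m} values inside [{t1y}, {t2y}] (need {min_inside})"
        )
    mean, sd = inside.mean(), inside.std()
    if sd == 0:
        raise FitError("inside-sample has zero variance")
    s1, s2 = inside.sum(), np.square(inside).sum()

    def nll(params):
        mu, log_s = params
        return _suffstat_nll(mu, np.exp(log_s), t1y, t2y, m, s1, s2)

    res = minimize(
        nll,
        x0=np.array([mean, np.log(sd)]),
        method="Nelder-Mead",
        options={"xatol": tolerance, "fatol": tolerance, "maxiter": 2000},
    )
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    if not res.success:
        raise ConvergenceError(
            f"truncated ML did not converge: {res.message}",
            last_iterate=(mu, sigma),
        )
    return mu, sigma


def ks_truncated(
    y: Sequence[float],
    model: Tuple[float, float],
    t1y: float,
    t2y: float,
) -> float:
    """KS distance between inside-observations and the truncated model.

    The empirical CDF of the observations inside [t1y, t2y]
    (renormalized on the interval, ties collapsed to single steps) is
    compared with the truncated-Gaussian CDF; the sup-difference is
    evaluated at both sides of every step, which is what makes heavily
    tied (rounded) data behave correctly.
    """
    if not t1y < t2y:
        raise DomainError("truncation bounds must satisfy t1y < t2y")
    mu, sigma = model
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    inside = y[(y >= t1y) & (y <= t2y)]
    if inside.size == 0:
        raise DomainError("no observations inside the truncation interval")
    vals, counts = np.unique(inside, return_counts=True)
    cum = np.cumsum(counts)
    m = cum[-1]
    Z = ndtr((t2y - mu) / sigma) - ndtr((t1y - mu) / sigma)
    if Z <= 0:
        return 1.0
    F = (ndtr((vals - mu) / sigma) - ndtr((t1y - mu) / sigma)) / Z
    right = cum / m
    left = (cum - counts) / m
    d = max(np.abs(F - right).max(), np.abs(F - left).max())
    return float(min(max(d, 0.0), 1.0))


# ---------------------------------------------------------------------------
# vectorized internals for the grid search
# ---------------------------------------------------------------------------

#: sigma cap, in units of the truncation-window width.  As sigma grows
#: the truncated normal tends to the uniform on the window, so the NLL
#: flattens and the MLE can sit at infinity (inside-sample more spread
#: than any truncated normal); such candidates are capped and kept —
#: their KS distance is what rules them out.
_SIGMA_CAP_WIDTHS = 20.0

#: fixed-point iterates within this relative step are close enough for
#: candidate *ranking*; the winner is always re-polished via scipy when
#: it has not met the strict tolerance.
_RANK_TOL = 1e-4


def _ml_fixed_point(a, b, m, mean, var, tolerance, max_iter=200):
    """Vectorized truncated-normal ML via accelerated moment matching.

    For each candidate interval k with bounds (a_k, b_k) and inside
    sample moments (mean_k, var_k), iterate the stationarity equations
    E[Y] = mean and E[(Y - mu)^2] = var + (mean - mu)^2 (the MLE of an
    exponential family matches its sufficient-statistic moments), with
    Aitken extrapolation every third step to accelerate the linear
    convergence.  Returns (mu, sigma, converged, acceptable) masks.
    """
    mu = mean.copy()
    sigma = np.sqrt(np.maximum(var, 1e-300))
    scale = np.maximum(sigma.copy(), 1e-12)
    cap = _SIGMA_CAP_WIDTHS * np.maximum(b - a, 1e-12)
    step = np.full(mu.shape, np.inf)
    hist_mu, hist_sg = [], []
    for it in range(max_iter):
        alpha = (a - mu) / sigma
        beta = (b - mu) / sigma
        Z = np.clip(ndtr(beta) - ndtr(alpha), 1e-300, None)
        pa, pb = norm.pdf(alpha), norm.pdf(beta)
        d1 = (pa - pb) / Z
        mu_new = mean - sigma * d1
        d2 = (alpha * pa - beta * pb) / Z
        denom = np.clip(1.0 + d2, 1e-6, None)
        var_about_mu = var + np.square(mean - mu_new)
        sigma_new = np.minimum(
            np.sqrt(np.clip(var_about_mu / denom, 1e-300, None)), cap
        )
        step = np.maximum(np.abs(mu_new - mu), np.abs(sigma_new - sigma))
        mu, sigma = mu_new, sigma_new
        hist_mu.append(mu)
        hist_sg.append(sigma)
        if len(hist_mu) == 3:
            # Aitken delta-squared on each parameter independently
            for hist, cur in ((hist_mu, "mu"), (hist_sg, "sigma")):
                x0, x1, x2 = hist
                d21 = x2 - x1
                dd = (x2 - x1) - (x1 - x0)
                ok = np.abs(dd) > 1e-300
                acc = np.where(ok, x2 - np.square(d21) / np.where(ok, dd, 1.0), x2)
                if cur == "mu":
                    mu = acc
                else:
                    sigma = np.clip(acc, 1e-300, cap)
            hist_mu, hist_sg = [], []
        if (step < tolerance * scale).all():
            break
    at_cap = sigma >= 0.999 * cap
    conv = (step < tolerance * scale) | at_cap
    acceptable = (step < _RANK_TOL * scale) | at_cap
    return mu, sigma, conv, acceptable


def _scan_lambda(lam, xd, w, cum0, I1, I2, n, res, cfg):
    """Score every candidate truncation pair at one lambda.

    Reported values are rounding-bin centers: a window [t1, t2] in
    reported units covers underlying values in (t1 - res/2, t2 + res/2),
    so the truncated model uses those bin *edges* as its bounds and the
    KS comparison matches empirical step sides against the model CDF at
    the corresponding edges.  Returns (best_score, best_k, mu, sigma,
    raw_ks) over the flattened pair index k; candidates with too few or
    degenerate insiders, or whose ML iteration failed to settle, score
    +inf.
    """
    yd = boxcox(xd, lam)
    ydlo = boxcox(np.maximum(xd - res / 2, xd / 2), lam)
    ydhi = boxcox(xd + res / 2, lam)
    cw = cum0[1:]
    ps1 = np.concatenate([[0.0], np.cumsum(w * yd)])
    ps2 = np.concatenate([[0.0], np.cumsum(w * yd * yd)])

    i1 = np.repeat(I1, I2.size)
    i2 = np.tile(I2, I1.size)
    a, b = ydlo[i1], ydhi[i2]
    m = cw[i2] - cum0[i1]
    s1 = ps1[i2 + 1] - ps1[i1]
    s2 = ps2[i2 + 1] - ps2[i1]
    valid = m >= cfg.min_inside
    msafe = np.where(valid, m, 1)
    mean = s1 / msafe
    var = s2 / msafe - mean * mean
    valid &= var > 0
    var = np.where(valid, var, 1.0)

    mu, sigma, _, acceptable = _ml_fixed_point(
        a, b, msafe.astype(float), mean, var, cfg.tolerance
    )
    valid &= acceptable
    # A healthy-component fit must be a *central* slice of its own
    # truncation window — a fitted mean outside [a, b] is a degenerate
    # far-tail slice (the exponential limit of the truncated normal),
    # not a physiological distribution.
    valid &= (mu >= a) & (mu <= b)
    # The transform image must cover the extrapolated central-95%
    # interval: lam*y + 1 > 0 at both limits.
    if abs(lam) >= 1e-8:
        z95 = 1.959963984540054
        valid &= lam * (mu - z95 * sigma) + 1.0 > 0
        valid &= lam * (mu + z95 * sigma) + 1.0 > 0

    # KS on the distinct-value grid, all pairs at once; only indices that
    # can fall inside some window matter.  Empirical right/left steps at
    # a reported value are matched against the model CDF at the value's
    # upper/lower rounding-bin edge.
    lo, hi = int(I1.min()), int(I2.max())
    sl = slice(lo, hi + 1)
    F_hi = ndtr((ydhi[sl, None] - mu[None, :]) / sigma[None, :])   # (D', K)
    F_lo = ndtr((ydlo[sl, None] - mu[None, :]) / sigma[None, :])
    Fa = ndtr((a - mu) / sigma)
    Fb = ndtr((b - mu) / sigma)
    Z = np.clip(Fb - Fa, 1e-300, None)

    idx = np.arange(lo, hi + 1)[:, None]
    in_win = (idx >= i1[None, :]) & (idx <= i2[None, :])
    emp_right = (cw[sl, None] - cum0[i1][None, :]) / msafe[None, :]
    emp_left = (cum0[lo:hi + 1, None] - cum0[i1][None, :]) / msafe[None, :]
    diff = np.maximum(
        np.abs((F_hi - Fa[None, :]) / Z[None, :] - emp_right),
        np.abs((F_lo - Fa[None, :]) / Z[None, :] - emp_left),
    )
    diff[~in_win] = 0.0
    ks = diff.max(axis=0)

    score = ks / np.sqrt(m / n) if cfg.penalize else ks.copy()
    score[~valid] = np.inf
    k = int(np.argmin(score))
    return float(score[k]), k, float(mu[k]), float(sigma[k]), float(ks[k])


def fit_kosmic(
    series: MeasurementSeries, config: Optional[KosmicConfig] = None
) -> KosmicFit:
    """Truncation-grid search over (lambda, q1, q2); smallest penalized
    KS wins.

    Candidate truncation bounds are sample quantiles q1 in
    [t1_min, t1_max], q2 in [t2_min, t2_max] on ``config.step``; lambda
    runs over ``config.lambda_grid`` and is then refined locally (golden
    section / Brent to ``config.tolerance``).  Deterministic.
    """
    cfg = config or KosmicConfig()
    if series.n < _HARD_MIN_N:
        raise InsufficientDataError(
            f"truncation-search fit needs at least {_HARD_MIN_N} values"
        )
    if series.n < _WARN_MIN_N:
        warnings.warn(
            f"n={series.n} < {_WARN_MIN_N}: truncation-search estimates "
            "will be unstable",
            stacklevel=2,
        )

    xd, w = np.unique(series.values, return_counts=True)
    if xd.size < 3:
        raise FitError("fewer than 3 distinct values")
    n = series.n
    res = series.resolution
    cum0 = np.concatenate([[0], np.cumsum(w)]).astype(float)

    # type-1 sample quantile -> index into the distinct-value grid
    def qidx(q):
        return int(np.searchsorted(cum0[1:], q * n, side="left"))

    q1s = np.round(np.arange(cfg.t1_min, cfg.t1_max + cfg.step / 2, cfg.step), 10)
    q2s = np.round(np.arange(cfg.t2_min, cfg.t2_max + cfg.step / 2, cfg.step), 10)
    I1 = np.unique([qidx(q) for q in q1s])
    I2 = np.unique([qidx(q) for q in q2s])
    I2 = I2[I2 > I1.min()]
    if I2.size == 0:
        raise FitError("degenerate quantile windows: data too discrete")

    failures = []
    best = None   # (score, lam, k, mu, sigma, ks)
    for lam in cfg.lambda_grid:
        try:
            score, k, mu, sigma, ks = _scan_lambda(
                float(lam), xd, w, cum0, I1, I2, n, res, cfg
            )
        except (FitError, DomainError) as exc:  # pragma: no cover - defensive
            failures.append((float(lam), str(exc)))
            continue
        if not np.isfinite(score):
            failures.append((float(lam), "no valid truncation window"))
            continue
        if best is None or score < best[0]:
            best = (score, float(lam), k, mu, sigma, ks)
    if best is None:
        raise FitError(f"all candidate fits failed: {failures}")

    # local lambda refinement around the grid winner
    grid = np.asarray(cfg.lambda_grid, dtype=float)
    gstep = np.diff(np.sort(grid)).max() if grid.size > 1 else 0.0
    if gstep > 0:
        lo = max(best[1] - gstep, float(grid.min()))
        hi = min(best[1] + gstep, float(grid.max()))

        def objective(lam):
            return _scan_lambda(lam, xd, w, cum0, I1, I2, n, res, cfg)[0]

        opt = minimize_scalar(
            objective, bounds=(lo, hi), method="bounded",
            options={"xatol": cfg.lambda_xatol},
        )
        if np.isfinite(opt.fun) and opt.fun < best[0]:
            score, k, mu, sigma, ks = _scan_lambda(
                float(opt.x), xd, w, cum0, I1, I2, n, res, cfg
            )
            best = (score, float(opt.x), k, mu, sigma, ks)

    score, lam, k, mu, sigma, ks = best
    i1 = np.repeat(I1, I2.size)[k]
    i2 = np.tile(I2, I1.size)[k]

    # polish the winner with the strict-tolerance scipy ML on the full
    # transformed sample (the fast path only needs ranking accuracy);
    # truncation bounds sit at the rounding-bin edges of the window
    y = boxcox(series.values, lam)
    t1y = boxcox(max(float(xd[i1]) - res / 2, float(xd[i1]) / 2), lam)
    t2y = boxcox(float(xd[i2]) + res / 2, lam)
    mu0, sigma0 = mu, sigma
    try:
        mu, sigma = truncated_gauss_ml(
            y, t1y, t2y, tolerance=cfg.tolerance, min_inside=cfg.min_inside
        )
        ks = ks_truncated(y, (mu, sigma), t1y, t2y)
    except ConvergenceError as exc:
        mu, sigma = exc.last_iterate
    escaped = not t1y <= mu <= t2y
    if abs(lam) >= 1e-8:
        z95 = 1.959963984540054
        escaped |= lam * (mu - z95 * sigma) + 1.0 <= 0
        escaped |= lam * (mu + z95 * sigma) + 1.0 <= 0
    if escaped:
        # polishing escaped along the degenerate far-tail direction;
        # keep the validated grid iterate instead
        mu, sigma = mu0, sigma0

    model = BoxCoxGaussian(lam=lam, mu=mu, sigma=sigma)
    return KosmicFit(
        model=model,
        t1=float(xd[i1]),
        t2=float(xd[i2]),
        ks=ks,
        ri=model_ri(model, method="kosmic"),
        score=score,
        quantile_window=(float(cum0[i1 + 1] / n), float(cum0[i2 + 1] / n)),
        n_inside=int(cum0[i2 + 1] - cum0[i1]),
    )
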