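"""Box-Cox transform machinery and the Box-Cox-Gaussian reference model.

The healthy ("non-pathological") component of a hospital analyte
distribution is modelled as Gaussian after a one-parameter Box-Cox power
transform:

    y = (x**lam - 1) / lam   (lam != 0),      y = ln(x)   (lam == 0),

with y ~ Normal(mu, sigma).  Reference limits in original units are then
closed-form percentiles: the p-th percentile is the inverse transform of
mu + z_p * sigma.  Both the truncation-search estimator and the
inverse-modelling estimator parameterize their healthy component this way,
so the model type and the percentile map live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.stats import norm

from .errors import DomainError

__all__ = [
    "boxcox",
    "inv_boxcox",
    "BoxCoxGaussian",
    "ReferenceInterval",
    "model_percentile",
    "model_ri",
]

# Below this |lam| the power branch suffers catastrophic cancellation;
# switch to the exact lam -> 0 limit (the natural log).
_LAMBDA_EPS = 1e-8


def boxcox(x, lam: float):
    """One-parameter Box-Cox transform of positive ``x``.

    Parameters
    ----------
    x : float or array-like, all entries > 0
    lam : float
        Power parameter.  ``lam == 0`` (and ``|lam| < 1e-8``) uses the
        log branch, the continuous limit of the power branch.

    Returns
    -------
    float or ndarray, matching the shape of ``x``.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise DomainError("boxcox requires strictly positive finite inputs")
    if abs(lam) < _LAMBDA_EPS:
        out = np.log(arr)
    else:
        out = np.expm1(lam * np.log(arr)) / lam
    return float(out) if np.isscalar(x) else out


def inv_boxcox(y, lam: float):
    """Exact inverse of :func:`boxcox`.

    Requires ``lam * y + 1 > 0`` when ``lam != 0`` (the image of the
    transform); raises :class:`DomainError` outside it.
    """
    arr = np.asarray(y, dtype=float)
    if abs(lam) < _LAMBDA_EPS:
        out = np.exp(arr)
    else:
        base = lam * arr + 1.0
        if np.any(base <= 0):
            raise DomainError(
                f"inv_boxcox undefined: lam*y + 1 <= 0 (lam={lam})"
            )
        out = np.exp(np.log(base) / lam)
    return float(out) if np.isscalar(y) else out


@dataclass(frozen=True)
class BoxCoxGaussian:
    """Healthy-component model: Normal(mu, sigma) on the Box-Cox scale.

    Attributes
    ----------
    lam : power parameter of the transform
    mu : mean of the transformed values
    sigma : standard deviation of the transformed values (> 0)
    """

    lam: float
    mu: float
    sigma: float

    def __post_init__(self):
        if not np.isfinite([self.lam, self.mu, self.sigma]).all():
            raise DomainError("model parameters must be finite")
        if self.sigma <= 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")

    def percentile(self, p: float) -> float:
        return model_percentile(self, p)

    def ri(self, method: str = "model") -> "ReferenceInterval":
        return model_ri(self, method=method)

    def cdf(self, x):
        """CDF in original units (0 for x <= 0 when the support starts there)."""
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(arr)
        pos = arr > 0
        y = boxcox(arr[pos], self.lam) if pos.any() else np.empty(0)
        out[pos] = norm.cdf(y, loc=self.mu, scale=self.sigma)
        # For lam < 0 the transform is bounded above by -1/lam; mass beyond
        # the image point accumulates at the upper bound.
        return float(out[0]) if np.isscalar(x) else out.reshape(np.shape(x))


@dataclass(frozen=True)
class ReferenceInterval:
    """A 2.5th-97.5th percentile reference interval in analyte units.

    ``ci_lower``/``ci_upper`` are optional bootstrap confidence intervals
    for the two limits, each an ordered ``(lo, hi)`` pair at ``ci_level``.
    """

    lower: float
    upper: float
    method: str = "model"
    ci_lower: Optional[Tuple[float, float]] = None
    ci_upper: Optional[Tuple[float, float]] = None
    ci_level: Optional[float] = None

    def __post_init__(self):
        if not (self.lower > 0 and self.upper > 0):
            raise DomainError("reference limits must be positive")
        if not self.lower < self.upper:
            raise DomainError(
                f"lower limit {self.lower} must be below upper {self.upper}"
            )
        for name in ("ci_lower", "ci_upper"):
            pair = getattr(self, name)
            if pair is not None:
                lo, hi = pair
                if not lo <= hi:
                    raise DomainError(f"{name} must be an ordered pair")

    def as_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "method": self.method,
            "ci_lower": list(self.ci_lower) if self.ci_lower else None,
            "ci_upper": list(self.ci_upper) if self.ci_upper else None,
            "ci_level": self.ci_level,
        }


def model_percentile(model: BoxCoxGaussian, p: float) -> float:
    """p-th percentile of the model in original units.

    Computed as ``inv_boxcox(mu + z_p * sigma, lam)`` with ``z_p`` the exact
    standard-normal quantile; strictly increasing in ``p``.
    """
    if not 0.0 < p < 1.0:
        raise DomainError(f"percentile level must be in (0,1), got {p}")
    y = model.mu + norm.ppf(p) * model.sigma
    try:
        return float(inv_boxcox(y, model.lam))
    except DomainError as exc:
        raise DomainError(
            f"percentile p={p} outside model support (lam={model.lam}, "
            f"mu={model.mu}, sigma={model.sigma})"
        ) from exc


def model_ri(model: BoxCoxGaussian, method: str = "model") -> ReferenceInterval:
    """Central 95% reference interval (2.5th and 97.5th percentiles)."""
    return ReferenceInterval(
        lower=model_percentile(model, 0.025),
        upper=model_percentile(model, 0.975),
        method=method,
    )
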