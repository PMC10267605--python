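"""Minimal diagnostic figures: probability plot and histogram-vs-model."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .boxcox import BoxCoxGaussian, ReferenceInterval
from .data_io import MeasurementSeries
from .hoffman import HoffmanFit, cumulative_plot

__all__ = ["probability_plot", "model_histogram"]


def probability_plot(series: MeasurementSeries, fit: Optional[HoffmanFit] = None,
                     ax=None):
    """Normal-probability plot with the fitted Hoffman line and RI markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v, z = cumulative_plot(series)
    ax.plot(z, v, ".", ms=2, color="0.4", label="observed")
    if fit is not None:
        zz = np.linspace(-2.2, 2.2, 50)
        ax.plot(zz, fit.intercept + fit.slope * zz, "-", color="C3",
                label=f"line (r$^2$={fit.r2:.4f})")
        for lim in (fit.ri.lower, fit.ri.upper):
            ax.axhline(lim, ls="--", color="C0", lw=0.8)
    ax.set_xlabel("standard-normal quantile")
    ax.set_ylabel(f"{series.analyte_name} ({series.unit})")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def model_histogram(series: MeasurementSeries, model: BoxCoxGaussian,
                    ri: Optional[ReferenceInterval] = None,
                    p_scale: float = 1.0, ax=None):
    """Histogram of the input with the estimated healthy-component curve
    and dashed lines at the reference limits."""
    import matplotlib.pyplot as plt
    from .refiner import _histogram, _bin_probs, _transform_edges

    if ax is None:
        _, ax = plt.subplots()
    edges, counts = _histogram(series)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.bar(centers, counts, width=np.diff(edges), color="0.8",
           edgecolor="none", label="observed")
    probs = _bin_probs(_transform_edges(edges, model.lam), model.mu, model.sigma)[0]
    ax.plot(centers, p_scale * series.n * probs, "-", color="C3",
            label="estimated model")
    if ri is not None:
        for lim in (ri.lower, ri.upper):
            ax.axvline(lim, ls="--", color="C0", lw=0.9)
    ax.set_xlabel(f"{series.analyte_name} ({series.unit})")
    ax.set_ylabel("count")
    ax.legend(fontsize=8)
    return ax
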