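# indirect-ri

Indirect reference-interval estimation from mixed hospital laboratory
data: computerised Hoffman, truncated Box-Cox-Gaussian fitting with
Kolmogorov-Smirnov truncation selection (KOSMIC-style), and
inverse modelling by multi-level grid search with bootstrap confidence
intervals (refineR-style) — plus a synthetic LIS-data generator with
known ground truth and a verification report against manufacturer (IFU)
ranges.

## The problem

A reference interval (RI) is the central 95% range — the 2.5th to
97.5th percentile — of an analyte in a healthy population.  Recruiting
a healthy cohort (the *direct* method) is expensive and often
impractical, so laboratories increasingly verify their in-use RIs
*indirectly*: they export every result of an analyte from the
laboratory information system (LIS) and estimate the healthy
component's percentiles from the mixed healthy/diseased distribution.
This package implements the three indirect estimators most commonly
compared for thyroid hormones (TSH, free T3, free T4), where
TSH's strong right skew and heavy pathological contamination make the
problem hardest.

## The model

All three estimators target the same healthy-component model: results
`x > 0` are Gaussian after a one-parameter Box-Cox transform,

    y = (x^λ − 1)/λ   (λ ≠ 0),   y = ln x   (λ = 0),   y ~ N(μ, σ²),

so the RI is closed-form: the p-th percentile in original units is
`inv_boxcox(μ + z_p σ, λ)` with `z_p` the standard-normal quantile.

* **Hoffman** (`fit_hoffman`) — fits a straight line to the central,
  linear portion of the normal-probability plot and extrapolates to
  z = ±1.959964.  The classical "visual" segment choice is replaced by
  a reproducible search: the widest quantile window with r² above a
  threshold.
* **Truncation search** (`fit_kosmic`) — for each candidate Box-Cox
  power λ and each truncation window (a pair of sample quantiles), fits
  a *truncated* Gaussian by maximum likelihood to the transformed
  inside-observations and scores it by the Kolmogorov-Smirnov distance
  between the renormalized empirical CDF and the truncated model CDF,
  penalized by the square root of the fraction of data inside.  The
  smallest penalized distance wins.
* **Inverse modelling** (`fit_refiner`) — locates the principal peak
  and a search region from a smoothed histogram, then runs a
  multi-level grid search over (λ, μ, σ, P), where P is the fraction
  of all results attributed to the healthy component, minimizing an
  asymmetric binned chi-square (pathological results can only add
  counts, so the model may never overshoot the observed histogram but
  is only weakly penalized for observed excess).  Confidence intervals
  come from a percentile bootstrap (200 resample-and-refit replicates
  by default).

## Worked example

The hospital datasets such studies draw on are not public, so the
package ships a generator whose defaults emulate an adult hospital TSH
population: a published healthy-component model (λ=0.07, μ=0.734424,
σ=0.688931, results rounded to 1 decimal, ground-truth RI
0.533–7.000 mIU/L) mixed with 5% suppressed-TSH (hyperthyroid-like)
and 25% elevated-TSH (hypothyroid-like) contamination:

```python
from indirect_ri import IFURange, run_comparison
from indirect_ri.synthetic import tsh_like_preset, generate

series, truth = generate(tsh_like_preset(n=50_000, seed=1))
print(f"ground truth: {truth.lower:.3f}-{truth.upper:.3f} mIU/L")
report = run_comparison(series, IFURange(analyte="TSH", lower=0.38, upper=4.28))
print(report.to_frame()[["method", "ri_lower", "ri_upper",
                         "dev_lower_pct", "dev_upper_pct", "verdict"]]
      .round(3).to_string(index=False))
```

prints

```
ground truth: 0.533-7.000 mIU/L
 method  ri_lower  ri_upper  dev_lower_pct  dev_upper_pct          verdict
hoffman     0.050     4.623        -86.842          8.012 lower-discordant
 kosmic     0.549     8.547         44.564         99.694  both-discordant
refiner     0.488     8.349         28.316         95.061  both-discordant
```

Read against the manufacturer range (0.38–4.28 mIU/L), the two
automated estimators report upper limits roughly twice the IFU value —
they track the contaminated upper tail of the mixture — while the
Hoffman line, extrapolated from the centre of a skewed distribution,
lands near the IFU upper limit but collapses the lower one.  Against
the *generator's* healthy truth (0.533–7.000), the automated methods
recover the lower limit well and overshoot the upper limit by ~20%,
while Hoffman undershoots both.  This is the behaviour such
method comparisons report on real thyroid data, reproduced here with
the truth known.

A command-line interface wraps the same flow:

```bash
indirect-ri simulate --spec spec.yaml --out data.csv
indirect-ri fit --method all --input data.csv --analyte TSH --out fits.json
indirect-ri compare --input data.csv --analyte TSH --ifu ifu.yaml --out report.csv
```

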