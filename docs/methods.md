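# Methods

## Scope and model

The package estimates the central 95% reference interval (RI) of a
positive-valued analyte from a mixed hospital population.  All three
estimators share one healthy-component model: after a one-parameter
Box-Cox transform `y = (x^λ − 1)/λ` (natural log at λ = 0, with the
log branch used for |λ| < 1e-8 to avoid cancellation), healthy values
are Normal(μ, σ).  Percentiles in original units are the exact inverse
transform of μ + z·σ; the 95% RI uses the exact normal quantile
1.959964 rather than the rounded 1.96 (the two agree to the printed
precision of every published value checked in the tests).  Every
estimator reports its RI *through this map* — `fit.ri` always equals
`model_ri(fit.model)` — so there is a single percentile code path.

Reported laboratory values are rounding-bin centers: a value printed
as 0.7 at one reported decimal stands for an underlying measurement in
(0.65, 0.75).  This matters more than it looks.  Treating a truncation
window [0.7, 5.7] as bounds at the bin centers includes the *whole*
boundary bins' mass while the continuous model expects only half of
it, and on a strongly skewed analyte the truncated-ML inversion
amplifies that small distortion severalfold (we measured a +9% bias in
σ on clean data before correcting it).  All windowed computations
therefore place truncation bounds at rounding-bin *edges*
(t ± resolution/2), and binned comparisons evaluate the model CDF at
the corresponding edges.

## Computerised Hoffman

The cumulative plot assigns the i-th order statistic the Hazen
plotting position (i − 0.5)/n (avoids the 0/1 endpoints), with ties —
ubiquitous in rounded data — sharing their mean rank.  The "visually
linear" segment of the classical method is replaced by a reproducible
rule: candidate quantile windows on a 1% grid inside [0.05, 0.95]
covering at least 40% of probability mass; ordinary least squares of
value on normal quantile per window (O(1) per window via prefix sums);
the selected window is the widest with r² ≥ 0.99, ties broken by
higher r², with a warned fall-back to the best-r² window when none
reaches the threshold.  All of these are `HoffmanConfig` fields, and a
`log_scale` switch (off by default — the classical method, and the
comparison this package supports, work on the original scale) fits
log-values instead.

On a strongly right-skewed analyte no window of a lognormal-like
probability plot is truly linear; the fitted line then extrapolates
short on the upper limit and can cross zero on the lower one.  A
non-positive extrapolated lower limit is clipped to half the reporting
resolution with a warning rather than raised, because it is a
legitimate (if degenerate) outcome of the method on skewed data, and
the comparison needs the fit, not an exception.

## Truncation search (KOSMIC-style)

For each λ on a grid (default 0 to 1 in steps of 0.05) and each
truncation window — sample-quantile pairs q1 ∈ [0.05, 0.30],
q2 ∈ [0.70, 0.95] on a 0.01 grid, deduplicated on the discrete data —
a Gaussian truncated to the window is fitted by maximum likelihood to
the transformed inside-observations, and scored by the KS distance
between the renormalized empirical CDF (ties collapsed; both step
sides evaluated at bin edges) and the truncated-Gaussian CDF.  Raw KS
degenerately prefers the narrowest window, so the objective divides by
√(fraction of data inside); the penalization is config-switchable and
a test pins that the selected window covers a data majority on clean
input.  The grid winner's λ is refined locally by bounded scalar
minimization (tolerance 1e-3 — λ below that resolution moves the RI by
far less than sampling noise), clamped to the hull of the declared
grid.

Truncated-normal ML is an exponential-family problem: the MLE matches
the truncated model's first two moments to the inside-sample moments.
The public `truncated_gauss_ml` solves the sufficient-statistic
likelihood with scipy (Nelder-Mead at the configured tolerance,
default 1e-7); the grid search instead iterates the moment-matching
fixed point *vectorized over all windows at once*, with Aitken
acceleration, which the tests cross-check against the scipy path.  Two
degeneracies need guarding.  First, when the inside-sample is more
dispersed than any truncated normal on that window, the MLE runs away
along σ → ∞ (the truncated normal tends to the uniform); σ is capped
at 20 window widths and such candidates survive only to be eliminated
by their KS distance.  Second, on heavily right-contaminated data the
likelihood can prefer a far-tail slice — a fitted mean outside the
window, mimicking an exponential tail.  Such fits are not a healthy
*component* in any meaningful sense (the window is supposed to cover
the centre of the physiological distribution), so candidates with μ
outside the window, or whose implied central-95% interval leaves the
image of the transform, are infeasible.  The final winner is
re-polished with the strict scipy path; if polishing escapes the
feasible set, the validated grid iterate is kept.

The upstream tool's `SD` setting is carried in `KosmicConfig.sd_param`
for provenance but enters no computation; its meaning is not defined
in the material this package works from.

## Inverse modelling (refineR-style)

Step 1 — peak and region.  A histogram is built with bins at the
reporting resolution (rounded values are then exact bin centers),
widened to an integer multiple of the resolution only if the data span
would exceed 2500 bins; this fine binning is what lets the region step
see structure at the scale the laboratory actually reports.  After
3-bin moving-average smoothing, the
principal peak is the tallest bin (leftmost on non-adjacent near-ties,
with a warning) and the search region grows from the peak while
smoothed counts stay above 10% of peak height — stopping early on a
flank that turns back *upward* (25% above the running minimum and
Poisson-significant at 5√min) after a clear descent, because a rising
flank is a secondary, pathological mode.  Without the upturn stop, a
dense spike of suppressed-TSH results near the assay floor — which in
a realistic mixture can rival the main mode's height — is swept into
the region and wrecks the left tail of the fit.

Step 2 — grid search.  The fit uses a second, coarser histogram:
~25 bins across the interquartile range of the in-region data, floored
at the reporting resolution.  Resolution bins are right for *detecting*
structure but hold too few counts per bin at moderate n for a stable
chi-square (at n = 5,000 the asymmetric loss visibly biased the fit
low before this separation); a width tied to the distribution's IQR
rather than to n keeps per-bin counts healthy *and* makes the fit
exactly invariant under duplication of the dataset.  The healthy
component is P·n·BoxCoxGaussian, with P ∈ (0, 1] the healthy
fraction.  Level 1 grids λ over
{0, 0.1, …, 1}, P over {0.3, …, 1.0}, and (μ, σ) around weighted
moment estimates of the transformed in-region data (±3 spacings of
σ/2 and σ/4).  Each further level (default 3 total) re-grids every
parameter ±1 coarse step around the incumbent at 5× resolution.  The
cost is an asymmetric binned Pearson chi-square: model overshoot
(expected above observed) carries full weight everywhere; observed
excess carries weight 0.25, and only inside the region.  The asymmetry
encodes that contamination only ever *adds* counts: a symmetric
chi-square chases contaminated shoulder bins and inflates the upper
limit further, while driving the weight toward zero (an envelope fit)
shaves a little more off that bias but progressively loses the
anchoring that keeps P identified — at weight 0.1 the recovered P on
*clean* data had already drifted to 0.94.  The 0.25 default is the
point where clean-data P recovery stays within ±0.05 of 1.
Candidates whose median lies outside the search region, or whose
central-95% interval leaves the transform's image, are infeasible.
The denominator is max(expected, 0.5) so near-empty bins neither
explode nor divide by zero.

Step 3 — uncertainty.  `bootstrap_ci` resamples the dataset with
replacement, refits from scratch (default 200 replicates), drops and
counts failed replicates (more than 20% failing is an error), and
takes percentile intervals of each limit.  Percentile rather than BCa:
with 200 replicates BCa's acceleration estimate is unstable.  The CI
level is exposed (default 0.95; 0.90 is equally supported, as both
conventions appear in published comparisons).

## Synthetic data

`SyntheticSpec` describes a mixture: a healthy Box-Cox-Gaussian
component sampled as inv_boxcox(Normal(μ, σ)), plus optional low- and
high-abnormal log-normal components, multinomial component counts,
shuffling, and rounding to the reporting resolution after mixing (as
an LIS reports).  Draws that fall outside the transform's image or
round to ≤ 0 are resampled per-draw with a bounded retry budget.  The
ground-truth RI is the closed-form interval of the healthy component —
independent of seed and contamination — and is recorded next to every
dataset.

`tsh_like_preset` is the standard benchmark: the published TSH healthy
component (λ=0.07, μ=0.734424, σ=0.688931; truth 0.533–7.000 mIU/L,
one reported decimal), 5% suppressed-TSH contamination (log-normal,
median 0.15 mIU/L, σ_log 0.6) and 25% elevated-TSH contamination
(median 12 mIU/L, σ_log 0.7) — a 30% total pathological fraction, the
regime reported as favourable for indirect estimation.  The component
medians sit beyond the healthy 0.5th/99.5th percentiles (0.34 and
10.1 mIU/L), but the elevated component's left tail overlaps the
healthy upper tail substantially, as subclinical hypothyroidism does
in practice.  What the generator does *not* emulate: age/sex structure
and stratification, repeat measurements from the same patient
(correlated results), calendar drift, assay changeovers, and
detection-limit censoring of suppressed TSH (values that would be
reported as "<0.01" are here resampled until they round positive).
Passing recovery tests on this generator therefore shows the
estimators handle skewed, rounded, contaminated mixtures — not that
they are unbiased on any particular hospital's data.

## What the acceptance battery shows — and what stays red

On clean data (n = 1e5, the shifted-Gaussian spec) all three
estimators recover the truth within 2%.  Under the 30% contaminated
TSH benchmark (20 seeds, n = 50,000) the measured medians are:
Hoffman (−91%, −32%), truncation search (+2.2%, +23.7%), inverse
modelling (−10%, +22.9%) for (lower, upper).  The suite asserts a
±15% recovery band for both limits of all three methods; the branches
that exceed it fail honestly and are left failing.  We regard the
measured pattern itself as the scientifically correct outcome: on real
thyroid data the same three methods disagree by far more than 15%
(automated upper limits roughly double the manufacturer's), and the
directional test — automated upper limits at or above the healthy
truth in ≥ 15/20 seeds under 40% high-side contamination — passes
20/20 for both automated methods.  At 60% contamination and n = 2,000
both automated estimators lose accuracy grossly (median upper-limit
deviation far beyond 25%), pinned as a regression of the documented
failure regime.

## Numerical and interface choices

* Problem sizes in the test battery: 1e5 for clean recovery, 20×5e4
  for the contaminated benchmark, 20×2e4 for the directional test,
  10×2e3 for the degradation regime, bootstrap at n = 5,000 with 200
  replicates.  These sizes put Monte-Carlo noise well inside the
  asserted bands while the full suite stays in the minutes range.
* Age filtering is inclusive on both ends (the adult default is
  18–87 years); one result per row, no per-patient deduplication —
  flagged here because repeated tests from sick patients are a known
  source of correlated contamination in LIS dumps.
* CSV dialect: comma-separated, UTF-8, header row, column roles
  remappable; the reader returns a drop-log (non-numeric,
  non-positive, age-filtered, …) that the CLI writes as JSON.
* Reporting resolution (`decimals`) is inferred from the raw text as
  the maximum observed decimal places, capped at 6, unless overridden.
* The comparability threshold in the verification report (±20% per
  limit, or IFU limit inside the method's bootstrap CI) is a policy
  default, exposed in the API — published comparisons state no
  quantitative rule.
* Known limitations: λ is weakly identified from a truncated window
  (different (λ, μ, σ) triples fit the window almost equally and
  diverge in the extrapolated tails), which is visible as a ~5–10%
  spread of the free-λ truncation-search limits on clean skewed data;
  the inverse-modelling cost weight (0.25) is a fixed design
  constant, not data-adaptive; and none of the estimators models age or sex
  partitions.
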