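# Methods

## The problem

Bird flight diverters are visual markers clipped onto power lines to
reduce bird collisions. Their effectiveness is usually estimated from
repeated carcass searches under marked and unmarked lines, classically with
a before–after (BA), control–impact (CI) or before–after control–impact
(BACI) field design. All three infer the diverter effect *indirectly*: they
assume that whatever changed between periods (or differed between sites)
other than the diverter cancels out. For BACI the critical assumption is
**synchronicity** — the relative change in bird flight intensity from the
before to the after period must be the same at the control and the impact
site. Flight intensity at a given line is driven by population fluctuations,
land use and weather, and can easily shift between sites in different ways;
when it does, BA and BACI estimates are biased and their type-I error rates
exceed the nominal level.

The **fusion design** removes the indirection: bird flight is monitored
alongside the carcass searches, and the carcass count of each search
interval is related directly to the observed flight intensity in that
interval. The period contrast then estimates a change in the *collision
rate per observed crossing*, which is immune to flight-intensity
fluctuations by construction.

## Data model and flight pooling

Two survey tables enter the analysis:

* carcass searches — one row per search, date and site, with the
  *corrected* carcass count (scaled upstream for persistence, searcher
  detection and off-transect mortality; typically non-integer) and the
  interval length in days since the previous search;
* flight counts — one row per observation session (counting point, date,
  species group, individuals counted, hours observed).

For the fusion analysis, every flight session falling in the half-open
interval `(previous search date, search date]` is pooled and attributed to
that search. The half-open convention prevents a session sitting exactly on
a search date from being counted twice. If an interval contains no flight
session, its carcasses and days roll forward until an interval with flight
data closes the observation, keeping the carcass window and the exposure
window aligned; a trailing run of searches never closed by flight data is
dropped. The exposure of a closed observation is

    A = interval_days × pooled_individuals / pooled_hours,

i.e. expected crossings over the interval given the observed hourly rate.

## Models

All models are fitted by maximum likelihood. The negative binomial (NB)
family uses the ecology parameterization `Var(Y) = μ + μ²/θ` (small θ =
strong overdispersion; the calibrated flight dispersion θ₁ = 0.41 only
makes sense in this convention). The likelihood is evaluated through
`lgamma`, so non-integer corrected carcass counts are admissible; they are
never re-rounded. Coefficients are estimated by iteratively reweighted
least squares (IRLS) with step-halving, alternated with one-dimensional
profile maximization of θ, to convergence of 1e-8 (max-norm on
coefficients) and 1e-6 (relative, on θ). θ is capped at 1e7; at the cap the
fit is numerically a Poisson fit, which is reported in the diagnostics.
Inference is Wald throughout: coefficient-level z tests and link-scale
confidence intervals.

The four estimators, each reporting the reduction `100·(1 − exp(β))`:

| method | data | linear predictor | β |
|---|---|---|---|
| BA | impact-site carcasses | `1 + period` | period |
| BACI | both sites | `1 + period + site + period:site` | interaction |
| NB fusion | impact-site fusion observations | `1 + period + offset log(1+A)` | period |
| B fusion | impact-site fusion observations | binomial logit, `1 + period` | period |

`log(1 + A)` rather than `log A` keeps zero-exposure intervals in the
model. The B fusion model forms per-observation event/non-event pairs
`round(c·carcasses/day)` vs `round(c·individuals/hour)`; `c` (default
10,000) is a rounding device for non-integer rates. Because `c` also
multiplies the nominal binomial sample size, it should be the *smallest*
value that makes the rates near-integer: inflating already-integer counts
by a large `c` shrinks the nominal Wald standard errors by √c and destroys
the calibration of the test. The simulation pipeline therefore uses `c = 1`
(its rates are integer counts over single-day, single-hour intervals).
Confidence intervals for the reduction are the link-scale Wald endpoints
pushed through the monotone map `β ↦ 100·(1−exp β)`, not a delta-method
approximation on the percent scale.

The synchronicity test applies the same NB ratio-of-ratios model to the
flight counts themselves (offset `log hours`); the `period:site`
interaction estimates the log of the factor by which the impact site's
between-period change exceeds the control site's, and
`100·(exp(β_int) − 1)` is the multiplicative bias a BACI carcass analysis
would inherit.

Real-data fits can adjust for seasonality via a cyclic cubic B-spline in
day-of-year (default 8 basis functions, equally spaced knots on [1, 366],
periodic to second derivatives, fitted unpenalized; one column dropped and
the rest grid-centered to avoid intercept confounding). The spline is off
in simulation mode, where no seasonal structure is generated.

## The simulator

The generator reproduces the study conditions calibrated to the geese data
of a German wire-marking study: per search interval, pooled flight counts
`F ~ NB(μ₁ = 1254, θ₁ = 0.41)` (drawn as a gamma–Poisson mixture for
robustness at small θ), and per crossing bird an independent collision with
probability `ζ = 0.001`. ζ is a rate per *observed* crossing — exactly the
quantity a fusion analysis estimates — not a true per-crossing collision
probability. Structural multipliers: Ω ≥ 1 lifts both sites' flight means
in the after period; Γ ≥ 1 additionally lifts the impact-after cell (the
synchronicity violation, which masks a true diverter effect in BA/BACI);
Λ ∈ [0, 1) multiplies the impact-after collision probability by (1 − Λ).
With partial detection, observed flights are an independent
`Binomial(F, detect_prob)` thinning while collisions remain driven by the
true `F`; expected carcass density is then unchanged, and the fusion
exposure is simply noisier.

Each dataset holds `n_obs_per_cell = 60` single-day intervals per
site × period cell. The value reconstructs the density of the calibrating
survey (roughly 250 pooled intervals across the four cells) and is exposed
as a parameter. Each interval spans one day with one observation hour, so
`A` equals the observed flight count; search-interval heterogeneity is not
simulated.

Scenario presets: `base`; `low_intensity` (μ₁/100, ζ×100 — sparse flights,
same carcass density); `high_variance` (θ₁ = 0.2); `partial_detection`
(detect_prob = 0.01).

Seeding: a master seed spawns one independent substream per dataset, so
results are bit-for-bit reproducible and invariant to which methods are
fitted.

## Performance evaluation

Metrics are computed at fixed parameter slices with exact binomial Monte
Carlo standard errors and Wilson intervals, not by smoothing a response
surface: false-positive rate (null datasets with two-sided p < α,
sign-agnostic), power (effect datasets with p < α *and* a sign-correct
positive reduction estimate), relative bias
`(mean reduction/100 − Λ)/Λ`, and the power ratio of two methods as the
ratio of their grid-averaged powers over Λ ∈ {0.1, …, 0.9} at Ω = Γ = 1.
α = .05 defines significance for effectiveness comparisons; the
synchronicity screen conventionally uses α = .1, and both are parameters.

A caveat on slice evaluation: summaries obtained by smoothing the power
surface over jointly sampled (Ω, Γ, Λ) — e.g. tensor-spline GAM fits
evaluated at the corner Ω = Γ = 1 — can report substantially larger
fusion/BACI power ratios than exact slice values, because the smoother
borrows strength from neighbouring regions where BACI power collapses
under synchronicity violation while fusion power is flat. Slice evaluation
is unbiased for the stated conditions and is what this package reports.

## What the generator does and does not emulate

It emulates: overdispersed pooled flight counts at realistic magnitude,
binomial collision thinning, period- and site-structured intensity shifts,
diverter action on the collision probability, and partial detection. It
does not emulate: seasonal structure, temporal autocorrelation, varying
search-interval lengths or observation effort, correction-factor
uncertainty in the carcass counts (counts enter as sharp values), or
spatial heterogeneity among counting points. Passing simulation tests
therefore validate the estimators under the stated stochastic model, not
under every complication of field data.

## Problem sizes and numerical choices

Monte Carlo sizes used by the test suite and the acceptance script: 1,000
null datasets per false-positive-rate check; 200 (tests) to 500 (script)
datasets per Λ grid point and scenario for power ratios; 250 per condition
for bias checks. At these sizes the binomial MC standard error of a rate
near .05 is ≈ .007 and each full run completes in a few minutes on one
core. Degenerate inputs are errors, not silent results: all-zero NB
responses, all-zero exposures, empty design cells, zero-variance Wald
tests. Non-converged fits are returned flagged (and recorded as
non-detections in the evaluation) rather than raised.

## Known limitations

* Wald inference with profile θ is slightly anticonservative in very small
  samples; the simulation conditions (≥120 observations per fit) are
  comfortably asymptotic.
* The unpenalized seasonal spline approximates the penalized smoothers
  often used for real survey data; real-data seasonal fits are
  approximate and the simulation study never exercises the spline.
* The B fusion model treats constructed event/non-event pairs as binomial;
  with `c` larger than needed its stated precision is optimistic (see
  above). The NB fusion model has no such artifact and is the recommended
  default.
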