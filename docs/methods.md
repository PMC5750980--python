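# Methods

## Heat-wave definition and indices

A day qualifies for an event when its daily mean temperature *reaches or
exceeds* the 95th percentile (`>=`), while the event's intensity day must
*strictly exceed* the 98th percentile (`>`); the asymmetry is deliberate
and fixed. Both thresholds are empirical quantiles of **all** calendar
days of the reference period (the "annual distribution"), not a
summer-only subset, using linear interpolation between order statistics
(`numpy.quantile` default). Leap days are pooled with everything else.

The excess-heat indices use backward-looking windows only: mortality on
day *i* can respond to heat on day *i* or earlier, never to upcoming days.
`EHIsig` is defined from day 3, `EHIaccl` and `EHF` from day 33; the first
32 days of a series are a warm-up with undefined values. An event whose
days overlap the warm-up is rejected by `summarize_heat_wave` with an
explicit error rather than silently summed; the pipeline keeps such events
in the detection table with empty heat-load columns and excludes them
listwise from the regressions (the exclusion count is reported).

Event heat loads are **raw sums** of the daily indices over event days:
negative daily `EHIsig` values (possible on the first days, where the
3-day mean reaches back before the event) are included; `EHF` is already
floored daywise, so its sum is non-negative.

## Direct age-standardization

Daily rates per 10,000,000 standard population are
`Σ_a (deaths_a / population_a) · w_a · 10⁷` over age bands, with the
classic European standard population aggregated to the two analysis bands
(0–64: 0.89, 65+: 0.11). Sex is never standardized over: male/female
series apply the age weights within sex, and the single-band groups (0–64,
65+) reduce to crude rates of that band. Populations are mid-year values
held constant within each calendar year.

## Baseline model

`log E(M_i) = α + s(t_i) + dow(i) + β·hwd_i`, fitted as a GLM with Poisson
log-likelihood on the (non-integer) standardized rates and dispersion
estimated from the Pearson chi-square — a quasi-Poisson fit. Choices:

* **Spline.** `s(t)` is a natural cubic regression spline (patsy `cr`) in
  a continuous day index with fixed degrees of freedom, default
  6 × n_years. Fixing df (rather than selecting smoothness by a criterion)
  keeps the baseline from chasing individual hot spells while absorbing
  trend and seasonality; `df_per_year` is configurable.
* **Day-of-week contrast.** Sum-to-zero, so α is a weekly-average level.
  Any full-rank contrast gives the same fit; this one makes the intercept
  interpretable.
* **Heat-wave indicator.** A single binary covariate pooled over all
  events; per-event effects are out of scope.
* **Counterfactual.** On heat-wave days the baseline is
  `exp(η_i − β)` = fitted/e^β; elsewhere it equals the fit. Removing the
  term therefore never changes non-heat-wave days.
* **Convergence.** IRLS, max 200 iterations; non-convergence raises with
  the deviance trace length. A df too large for the data span is rejected
  up front.

## Excess mortality and confidence limits

Cumulative excess is Σ(observed − baseline) over event days. The 95%
interval uses the exact (Garwood) Poisson limits via the count–chi-square
relation, L = χ²(α/2; 2O)/2 and U = χ²(1−α/2; 2(O+1))/2, applied to the
**observed** event total O and shifted by the baseline total E:
(L − E, U − E). The standardized total is rounded to the nearest count for
the limit computation only; raw values are used everywhere else. An event
is flagged significant when 0 lies outside the interval. Exact coverage of
these limits at μ = 50, computed by summing the Poisson mass, is 95.26% —
the well-known slight conservatism of exact intervals. Report tables round
percentages half-up to 1 decimal and counts to integers; by construction
ØRMD · duration = ∑RMD exactly.

## Extended heat-wave periods

Deviations are smoothed with a 3-day centered moving average (undefined at
series ends). The EHP starts at the first day of the contiguous positive
run reaching back from the event start (contiguous-run semantics: the scan
stops at the first non-positive day, not at the nearest positive window
further back). The positive phase ends with the contiguous positive run
after the event end; the negative phase extends while the smoothed value
stays negative. A smoothed value of exactly **zero terminates a phase**
(boundary-inclusive reading of "drop below zero"). Successive events whose
gap never drops to ≤ 0 merge into one EHP; report tables mark absorbed
events with `---`. Scans are capped at 30 days from the event
(configurable) to prevent runaway periods on pathological series; forward
scans also stop at the next unmerged event. If the smoothed deviation at
the event start is not positive, the EHP degenerates to the event itself
and is flagged. Displaced mortality, 100·|negative sum|/positive sum, is
undefined (flagged) when the positive-phase sum is non-positive; with a
post-event deficit exactly offsetting the excess it equals 100% — the
pure-harvesting limit.

Phase delimitation uses relative deviations (%); since the baseline is
positive, sign patterns — and hence the phases and the displacement ratio,
which is scale-invariant — are identical to those of absolute deviations.

## Association analysis and group comparison

Per-event ∑RMD is regressed on one characteristic at a time by OLS, with
R², the two-sided slope p-value and a pointwise 95% band of the fitted
line. At least 3 events with a defined predictor are required; a constant
predictor is rejected. Group mean impacts are compared with the Welch
(unequal-variance) two-sample t-test on per-event mean RMDs; two
zero-variance samples are flagged degenerate rather than tested.

## Synthetic data

The generator supplies inputs with the structure the analysis assumes; its
defaults describe a Czech-scale national registry and were chosen once:

* **Temperature.** Annual mean 9 °C with seasonal semi-amplitude 10 °C
  (peak mid-July), plus stationary AR(1) noise with φ = 0.7 and marginal
  sd 2 °C — lag-one persistence of that order is what makes multi-day
  exceedance runs realistic. `noise_sd` is the marginal sd; innovations
  have sd `noise_sd·√(1−φ²)`. Heat episodes are flat additive bumps;
  episodes outside the simulated range are rejected.
* **Mortality.** Per-stratum Poisson counts with log-mean =
  log(300 deaths/day) + secular trend (−0.5%/yr) + winter-peaked seasonal
  cycle (±10%, peak mid-January) + weekly cycle (sum-to-zero offsets, max
  Monday +2%, min Sunday −2.5%) + heat term. The heat term is selectable:
  a constant log offset on heat-wave days (default 0.12, the generative
  counterpart of the model's binary indicator) or proportional to daily
  EHF (default 0.01 per °C², used to probe the heat-load association).
  Stratum shares of deaths (≈49/51 by sex, ≈22/78 by age) follow typical
  national natural-cause registry totals under sex × age independence.
* **Population.** 10.5 M total; stratum shares drift linearly so the 65+
  share rises from 13% to 18% across the simulated years, evaluated at
  mid-year and held constant within each calendar year.
* **Reproducibility.** Temperature and mortality draw from independent
  child streams of the configured seed; fixed seed ⇒ bit-identical output.

The pipeline feeds the **detected** heat-wave days of the generated
temperature series into the mortality generator, so the generative
indicator coincides with the analysis-side indicator — parameter-recovery
experiments then test estimation, not event-definition mismatch.

What the generator does **not** emulate: influenza winters, air-pollution
covariation, cause-of-death structure below "natural causes", multi-station
spatial averaging, or overdispersion beyond Poisson. Passing tests
therefore validate the pipeline's arithmetic and estimation behaviour
under the assumed structure, not the epidemiology of any real population.

## Problem sizes and experiment design

Simulation-based checks use 5–6-year daily series (≈1,800–2,200 days,
≈300 deaths/day, ~2 injected summer episodes per year): long enough for a
30–36-df spline baseline and ~10 events per run, small enough that the
full suite and the reproduction script each run in well under a minute.
The heat-effect recovery experiment uses 100 (test) / 50 (script) seeded
datasets; interval coverage uses 10,000 draws at μ = 50.

## Known limitations

* The quasi-Poisson variance on *standardized* rates is an approximation:
  standardization mixes stratum counts with unequal weights, so the true
  variance is not exactly proportional to the mean. The Pearson-scale
  correction absorbs most of this in practice (recovery experiments show
  ~95% nominal coverage of the heat-effect CI).
* Exact Poisson limits are slightly conservative by construction.
* The displacement estimate inherits all caveats of deviation-sign
  delimitation: it bounds, rather than identifies, short-term harvesting,
  and single-day sign flips move phase boundaries.
* No distributed-lag exposure–response modelling, no temperature term
  beyond the binary indicator, and no alternative heat-wave definitions
  (humidity-based indices etc.).
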