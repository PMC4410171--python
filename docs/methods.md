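# Methods

## Data model

The unit of input is an annual registry record: calendar year, number of
newly diagnosed patients (`new_cases`), population aged ≤19
(`pop_under19`), and number of 19-year-olds (`pop_19`). Tables must be
gap-free and hold at least two years; a trailing year may carry population
data only (the packaged Slovenian series has counts for 1997–2012 and
population data through 2013). All computation uses full-precision ratios
derived from the counts — the annual incidence rate
`100000 · new_cases / pop_under19` and the aging-out proportion
`pop_19 / pop_under19` — never display-rounded rates; this is what makes
the fitted parameters reproducible to several significant figures.

## Incidence-trend models

Two trend families are fitted to the rising era (default window
1997–2003, ≥3 usable years required):

- **Linear**: ordinary least squares of the rate on `t = year − origin`,
  with the origin at the window start so the intercept `a` is the fitted
  rate in the first year and `b` the annual increment (per 100 000 per
  year). `r²` is the ordinary coefficient of determination on the rate
  scale.
- **Exponential**: log-linear least squares — OLS of `ln(rate)` on `t`,
  with `A = exp(intercept)` (rate at the origin) and `k` the rate constant
  per year. `r²` is reported on the log scale, where the fit is performed.
  Nonlinear least squares on the natural scale was deliberately not used:
  log-linear OLS is the standard, closed-form estimator for a
  constant-relative-growth process with multiplicative errors, and it is
  the variant whose parameters the reference analysis reports. A zero or
  negative rate anywhere in the window is a domain error.

Shifting the time origin by `d` years multiplies the exponential intercept
by `e^{k·d}` and leaves `k` unchanged; a property test pins this
reparameterisation.

The plateau era (default 2004–2012) is summarised by the sample mean, SD,
and a Student-t 95% CI, `mean ± t(n−1, 0.975)·sd/√n`. The t interval, not
the normal one, matters at n = 9: it reproduces the reference interval
(67, 87) where a normal interval would give roughly (69, 85).

### Scenario assembly

Each scenario's full incidence series uses **observed** rates throughout
the plateau era; fitted values replace observation only in the rising era,
and backward extrapolation applies only to the exponential scenarios
(negative exponents down to the 1987 or 1980 start year). The linear
scenario is clamped at zero before the first observed year rather than
extended down the line to its root (~1993): the zero-before-1997
convention is part of that scenario's definition, and extending the line
would conflate two different assumptions about the unobserved era. Rates
before a scenario's start year are zero by convention.

## Prevalence recursion

`P(n) = P(n−1)·(1 − G(n)) + I(n)`, with `P(start) = I(start)` (zero
prevalence before the first year of nonzero incidence). The model has no
remission, mortality or migration terms — diagnosis is permanent until the
patient ages out at 19 — so the only outflow is `G`. Working in rate space
(per 100 000) avoids needing pre-registry population counts; absolute case
counts are formed only at reporting time, as `rate × pop / 100000`, with a
display convention of rounding counts to the nearest 50 and rates to the
nearest 10.

Design choices worth recording:

- **Order of operations.** Outflow is applied to last year's pool before
  adding this year's newly diagnosed (new 19-year-old diagnoses are not
  immediately discounted). The alternative order,
  `(P(n−1) + I(n))·(1 − G(n))`, differs by under 6% on the reference data;
  the adopted order is the one that reproduces the reference 2012 and 2020
  estimates.
- **Pre-registry G.** For years before the first observed year (needed by
  the 1987- and 1980-start scenarios) the aging-out proportion is frozen
  at its earliest observed value. Cohorts diagnosed before 1997 are almost
  entirely aged out by 2012, so the 2012 estimate moves by well under 1%
  when this fill value is varied across a plausible range (a test
  demonstrates this).
- **CI propagation.** The recursion is re-run twice with the plateau CI
  bounds substituted for the incidence rate from the plateau's first year
  onward; earlier years keep their point incidence, since the plateau CI
  describes only the plateau era. Monotonicity of the recursion in `I`
  guarantees the resulting trajectories bracket the point estimate
  wherever the substitution applies.
- **Cross-scenario summary.** The headline estimate is the arithmetic mean
  of the four scenarios' point estimates; robustness is reported as the
  relative deviation `(max − min)/mean`. Fold-change reporting uses the
  1980-start exponential scenario, the deepest extrapolation and the one
  least sensitive to the start-year cutoff.

## Forward projection

From the last observed year the recursion continues with incidence fixed
at the plateau mean and `G` fixed at the arithmetic mean of the last three
observed years. Under these constants the trajectory contracts
geometrically toward the fixed point `I/G` from below and cannot overshoot
it. The population aged ≤19 is projected with a constant annual factor
equal to the **geometric** mean of the trailing three year-over-year
ratios — the natural choice for a geometric growth model, though with
ratios this close to 1 the arithmetic mean differs only in the sixth
decimal. CI trajectories are continued with the plateau CI bounds as the
constant incidence. Population projection is treated as deterministic; no
uncertainty is attached to it.

## Synthetic registry generator

`SyntheticConfig` defaults describe a registry like the packaged one: rate
rising as `A·e^{kt}` (A = 30 per 100 000, k = 0.141/year) through 2003,
then a plateau at 77 per 100 000; population starting at 492 000 and
declining 1.2%/year; aging-out level 6% with optional jitter; annual case
counts either the rounded expectation (`noise="none"`) or Poisson draws
with that expectation (`noise="poisson"`); a single seeded generator per
table. Case counts are integers, so even the noiseless table carries up to
half a count of rounding per year (relative error < 0.3% at these
magnitudes); the generator therefore also exposes its exact rate curve
(`true_incidence_series`) for machine-precision end-to-end checks against
the closed-form cohort sum. The generator deliberately omits
overdispersion, reporting delay and diagnostic drift, because the fitted
model contains no such terms — passing synthetic tests shows the pipeline
is internally consistent, not that real registries satisfy the model.

The recovery harness defines truth as the pipeline's output on the
noiseless expectation table (identical to the generating parameters up to
count rounding), making bias and RMSE exactly zero in the noiseless case
and centring Poisson-noise experiments correctly. At registry-scale
populations (~400 000), 500 Poisson replicates recover the exponential
rate constant with mean error well inside 10%.

## Numerical and interface choices

- OLS via `scipy.stats.linregress` (closed-form, no iteration); t
  quantiles via `scipy.stats.t`; no tolerances to tune anywhere in the
  pipeline — every estimator is closed-form and the recursion is exact
  arithmetic.
- Degenerate inputs: zero variance in the plateau window collapses the CI
  to the mean; a zero rate anywhere in an exponential window is an error
  rather than silently dropped; fold changes with a zero base are errors.
- Exported CSV/JSON files are written at full precision; rounding happens
  only in the human-readable report.
- Test and acceptance problem sizes (500-replicate recovery runs, ~200-year
  steady-state horizons) were chosen as the smallest sizes at which the
  Monte-Carlo and asymptotic claims are comfortably resolved; the whole
  suite runs in a few seconds.

## Limitations

- The model identifies *diagnosed* prevalence, not true prevalence; any
  diagnostic drift, under-ascertainment or miscoding in the registry is
  inherited untouched.
- Permanence of diagnosis until 19 is an approximation; remission,
  emigration and death all bias estimates upward, re-diagnosis of the same
  child would bias them upward too.
- The plateau CI treats the nine plateau rates as i.i.d.; autocorrelation
  in annual rates would widen the true interval.
- The backward extrapolations are untestable by construction — the
  scenarios bound the uncertainty (the cross-scenario deviation is the
  honest summary of it) rather than resolve it.
- The projection assumes the plateau persists; a renewed rise in incidence
  would make the 2020-style projections lower bounds.
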