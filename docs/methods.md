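# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `lungpcm`, and what the bundled synthetic scenario
does and does not establish about real registry data.

## Incidence trend model

Within each stratum (country × sex × five-year age cohort, ten cohorts from
40–44 to 85+), the crude incidence rate per 100,000 is modelled as

    ln r(t) = b0 + b1·t + Σ_j c_j·(t − τ_j)+

a continuous piecewise-linear function of calendar year with hinge years
τ_j (joinpoints). Each segment's slope maps to an annual percent change,
APC = 100·(e^slope − 1). Fitting is ordinary least squares on ln(rate)
with homoscedastic errors; no population weighting is applied because no
variance model is available for the input rates (this is configurable in
the sense that the fitting functions accept any series).

**Joinpoint selection.** Candidate joinpoints sit at observed years with at
least two observations in the interior of every segment. The number of
joinpoints (0–2, default maximum 1 for the 8–13-point series the scenario
produces) is chosen sequentially: k vs k+1 is compared by a permutation
test — residuals of the best k-joinpoint fit are permuted, added back to
its fitted values, and the relative SSE improvement of the best (k+1)-model
is recomputed for each of n_perm = 499 permutations; the add-one p-value is
compared against α/max_joinpoints (Bonferroni across the selection
sequence). Ties in SSE are broken toward fewer joinpoints, then the
earlier joinpoint year. When the smaller model already fits exactly
(relative SSE below 1e−12), no further joinpoints are added; this makes
noise-free series recover their generating APC exactly. A type-I error
simulation (500 null series, 5% noise) keeps the spurious-joinpoint rate
within Monte Carlo slack of the nominal α.

**Projection.** Rates beyond the last data year compound the *last*
segment's APC from the model-fitted (not observed) rate at the last data
year, regardless of the segment's statistical significance. Years before
the first data year extend the first segment's line backwards (reverse
compounding), which supplies the pre-2000 early-stage cohorts that the
ten-year progression window needs. Both extensions are simply the
evaluation of the piecewise-linear log-rate outside the data range.
Per-segment APC confidence intervals and p-values are Wald-type, using a
QR-based covariance (calendar-year design matrices are ill-conditioned for
normal-equation inversion).

## Cascade

Incident counts (rate/100,000 × population, per stratum, summed to country
level) pass through a multiplicative chain: NSCLC share → stage
distribution with the "unknown" mass redistributed pro rata across I–IV
(a `drop` mode exists for sensitivity checks) → IIIA/IIIB split of stage
III → early (I, II, IIIA) vs advanced (IIIB, IV). Early cohorts from the
previous ten diagnosis years contribute progression events with annual
probabilities F(d) − F(d−1) from a per-stage Weibull CDF
F(t) = 1 − exp(−(t/α)^β) (α scale in years, β shape — conventions differ
between software packages; this one matches the scale/shape naming used in
survival analysis). The scale is solved in closed form from the published
five-year cumulative recurrence anchor, α = 5/(−ln(1−p₅))^(1/β); the shape
defaults to 1 (exponential) for all three stages because the cumulative
curves behind the published anchors are not available in tabular form —
`fit_weibull_shape` performs the bounded least-squares shape fit (β ∈
[0.2, 5], scale re-anchored at every candidate) when a curve is supplied.
Patients without recurrence by year 10 are treated as cured (hard
truncation, not a mixture-cure fraction).

Progression is applied per stage with stage-specific anchors rather than to
a pooled early cohort, since the recurrence data are stage-specific.

The advanced pool (de novo + progressed, attributed to the calendar year of
advanced-disease entry) is multiplied by the systemic-eligibility share
(88.3%; 11.7% receive best supportive care only), the histology split, and
per-histology first/second/third-LOT rates, read as unconditional
proportions of the eligible advanced pool. First-line counts are computed
but not reported by default. An optional *survival-lag* mode defers half of
each year's second/third-LOT counts to the following year and weights both
halves by survival to a 6-month treatment lag using the per-histology
mortality Weibull (exponential by default, anchored on median OS of 6.0 /
9.4 months); it is off by default because the published description of how
mortality enters the counts is not specific, and varying OS was reported
not to move the estimates materially.

Reported tables are rounded to the nearest 100 patients; all internal
arithmetic is unrounded.

## Synthetic scenario and calibration

Registry extracts and UN population projections cannot be redistributed, so
the bundled scenario emulates their structure with known ground truth:

- **Trends:** each stratum follows a single-segment geometric trend whose
  APC equals the published last-segment estimate for that stratum, over the
  country's registry coverage years (France/Germany 2000–2012, Italy
  2000–2009, Spain 2000–2007), with multiplicative lognormal observation
  noise (unit mean, CV 0.02 by default; registry rates are positive with
  roughly constant relative error).
- **Demographics:** synthetic baseline rates (male several-fold female,
  strongly age-increasing — realistic orders of magnitude for western
  Europe around 2000) and populations with constant per-stratum growth
  rates that emulate cohort aging; both extended 1990–2030 by the same
  geometric rule.
- **Calibration:** the cascade is exactly linear in the incidence level, so
  one unscaled run per country yields the factor that makes the 2016
  deterministic second-LOT count equal the published anchor (France 11,600;
  Germany 15,100; Italy 13,500; Spain 9,400). Calibration fixes only the
  level; growth rates, histology/LOT structure and interval widths are
  untouched model outputs.

Consequently, passing tests demonstrate internal correctness (exact
arithmetic, parameter recovery, calibrated anchors, statistical calibration
of the selection test and PSA) — they do not validate the published 2020
projections, which depend on the original registry inputs and the original
trend-software settings, neither of which is published. The scenario's 2020
outputs land close to the published ones, but that closeness is a property
of the synthetic baseline, not a reproduction.

## Probabilistic sensitivity analysis

Each simulation draws: proportions (NSCLC share, histology, IIIB share,
eligibility, LOT rates, five-year recurrence anchors) from beta
distributions parameterized by method of moments from a mean and 95% CI;
the five-component stage vector from a Dirichlet with concentration
proportions × effective sample size; last-segment APCs from normal
distributions with delta-method standard errors from the trend fits; and
median OS from a truncated normal. Recurrence and OS draws are propagated
through the Weibull recalibration rather than perturbing α and β directly,
since no standard errors for the shape/scale are available. Published
tables do not state input CIs, so proportion CIs default to ±10% relative
half-width and the Dirichlet effective sample size to 100 — both are
configuration fields (`psa.rel_halfwidth`, `psa.stage_ess`), and setting
the half-width to 0 reproduces the deterministic run exactly.

1000 simulations (the default) summarize each country/year/LOT cell by the
mean and the 2.5th/97.5th percentiles. Simulations use RNG substreams
spawned from the master seed, so results are independent of execution
order. A drawn parameter set that violates an invariant (e.g. independent
LOT-rate draws breaking third ≤ second ≤ first, possible only in extreme
tails) fails validation and is dropped; more than 5% drops aborts the run.
In practice the drop rate at default widths is ≈0.1%.

## Numerical choices and degenerate inputs

- Log-linear fits require ≥ 3 observations and strictly positive rates;
  shorter series raise `InsufficientDataError`, non-positive rates a
  `DomainError`. Requesting more joinpoints than the series supports
  reduces the maximum and records a warning on the fit object.
- Exact fits (SSE ≤ 1e−12) get zero slope SE, a p-value of 0 for non-zero
  slopes, and degenerate CIs, avoiding spurious inference from floating
  noise.
- Weibull calibration rejects anchors outside (0, 1); `beta_from_mean_ci`
  falls back to a point mass (with a warning) when the stated CI implies
  more variance than a beta distribution can carry.
- An all-unknown stage distribution is a degenerate-distribution error.
- Totals are accumulated in plain left-to-right order so that a
  zero-variance PSA reproduces deterministic totals bit-for-bit.

## Problem sizes used in the test suite

The suite exercises the scenario at the sizes the methods are designed for:
80 strata × 8–13 years for full four-country runs, 500-replicate null
simulations for the selection test, 1000-simulation PSAs, and 50-replicate
end-to-end parameter-recovery runs at 200 simulations each. The whole suite
runs in well under a minute on one CPU.

## Known limitations

- Joinpoint feature set is deliberately minimal: no autocorrelated-error
  models, jump models, or averaged APC across segments.
- Progression ignores competing mortality before relapse, and cure is a
  hard 10-year truncation.
- LOT rates are treated as exchangeable between de novo and progressed
  advanced patients.
- The synthetic scenario's demographics are stylized (constant per-stratum
  growth); real population projections have cohort structure the generator
  does not emulate.
- Screening-driven stage shifts and mutation-status stratification are out
  of scope.
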