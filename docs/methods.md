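# Methods

## Model

The projection rests on a non-homogeneous Markov illness-death model with
states non-demented (0), demented (1) and dead (2), stratified by sex and by
an irreversible binary exposure z (chronic benzodiazepine use, i.e. six or
more consecutive months of dispensing).  Intensities are proportional in the
exposure:

- dementia incidence `α01(a,t,z) = α01⁰(a,t) · θ01^z`,
- mortality of non-demented `α02(a,t,z) = α02⁰(a,t) · θ02(a)^z`,
- mortality of demented `α12(a,t,z) = α02⁰(a,t) · RR(a) · θ12(a)^z`,

where `a` is age, `t` calendar year, `RR(a)` the age-specific relative risk
of death for demented versus non-demented subjects.  Exposure is acquired at
65 (Bernoulli draw against the age-65 prevalence) or later (age-specific
incidence of chronic use) and never lost; the model's assumptions are that
the exposure effect is causal, lifelong, and identical in both dementia
strata for mortality (`θ02 = θ12`).

## Parameters that matter

| parameter | meaning | default | units |
|---|---|---|---|
| `theta01` | dementia relative risk of exposure | 1.6 | — |
| `theta_mort` bands | mortality RR of exposure, 5-year bands from 65 | 2.45, 1.69, 1.30, 1.10, 1.00 | — |
| `trend_rate` | generational decline of dementia incidence | 0.01 | /birth year |
| reference generation | anchor of the incidence curve | aged 75 in 1990 (born 1915) | — |
| `intervention_year` | first year scenarios act | 2020 | calendar year |
| `n_per_cohort` | simulated subjects per birth cohort and sex | 10,000 | — |
| `n_ci_runs` | resampled projections for CIs | 100 | — |
| target year | year the indicators describe | 2040 | calendar year |
| cohorts | birth years followed | 1935–1975 | — |

All hazards are continuous-time intensities per person-year; the engine
converts them to annual probabilities with `1 − exp(−rate)`.

## Calibration from population-average inputs

**Generational trend.**  The input incidence curve belongs to the reference
generation; cohort `b` uses `α01(a) · (1 − trend_rate)^(b − 1915)`.  Indexing
the trend on birth year is equivalent to a 1%-per-calendar-year decline at
fixed age.  The `no_trend` switch reproduces the constant-incidence
sensitivity analysis.

**Mortality split.**  Overall mortality `μ(a,t)` is split into strata per
cohort (along the diagonal `t = b + a`): starting from dementia prevalence
π(65) = 0 among the alive, each age solves `μ = (1−π)·α02 + π·RR·α02` for
`α02`, sets `α12 = RR·α02`, and advances π with the engine's own one-year
kernel (death before dementia within the year).  This is the exact
discrete-time analogue of the continuous-time differential-equation
approach; because the projection itself runs in annual steps, the discrete
split is self-consistent, and `(1−π)α02 + πα12` reproduces the input μ to
machine precision at every cell.  The split is done per cohort rather than
per period, consistent with the cohort-wise simulation.

**Exposure mixture.**  Unexposed baselines come from inverting
`α = P·α⁰·θ + (1−P)·α⁰`, with `P` the prevalence of (past or current)
exposure among alive non-demented subjects for `α01`/`α02` and among alive
demented subjects for `α12`.

**Two-pass algorithm.**  `P` is not an input: a first simulation pass runs
with population-average intensities and the exposure process switched on but
effect-free, solely to estimate the exposure-prevalence surfaces by cohort
and age; the second pass uses the calibrated baselines.  Exactly two passes
are run, no iteration to convergence.  The first pass always uses the
status-quo exposure process, whatever scenario is projected: the prevalence
in the mixture identity describes the population in which the
population-average rates were estimated, so the unexposed baselines are
shared across scenarios.  (Calibrating each scenario against its own
prevalence would rescale the baselines so that the population-average
incidence is reproduced under every scenario, cancelling the intervention by
construction.)  `run_two_pass` accepts `calibration_scenario` to override
this.  Zero-alive cells in the prevalence surfaces are filled by carrying
the nearest defined age of the same cohort; cohorts with no demented
subjects at all fall back to the non-demented surface.

## Simulation conventions

- Within a year, events are drawn in the order exposure → death → dementia.
- Rates for the year starting at age `a` of cohort `b` are read at
  `(a, b + a)`; event ages are recorded as the age attained that year.
- The death draw uses the dementia status from the previous year's end
  (dementia acquired in the same year's third step cannot kill that year),
  so onset always strictly precedes death in recorded ages.
- A newly exposed subject uses exposed rates for that same year's death and
  dementia draws (the literal sequential reading; switchable only by editing
  the kernel, which the oracle shares).
- Scenario gating: the intervention multiplier applies to risk intervals
  whose starting calendar year is at or after the intervention year.
- The mortality projection ends in 2070 while the youngest cohorts are
  followed to 2080; cohort diagonals carry the last projected calendar year
  forward.
- Three uniform variates are consumed per subject-year regardless of state,
  so runs with a common seed are coupled draw-for-draw across scenarios
  (common random numbers).

## Indicators

All for a target year T (default 2040), per sex and scenario:

- **Prevalence (counts by age, total, rate)** — cross-sectional over ages
  65–99: at age `a` the cohort born `T − a`, weighted by
  `pop65(b+65)/n_per_cohort`; the rate is weighted demented over weighted
  alive, in percent.
- **Lifelong probability of dementia at 65** — fraction of the cohort aged
  65 in T that ever develops dementia (followed to 105), in percent.
- **Life expectancy without dementia at age a** — among subjects of the
  cohort aged `a` in T who are alive and non-demented at `a`, the mean
  number of later attained ages (≤ 105) at which they are still alive and
  non-demented.  Whole person-years; no half-year continuity correction.
  These are cohort life expectancies under each cohort's own projected
  future rates, not period (Sullivan-type) quantities.
- **Mean age at dementia** — mean onset age among demented subjects of the
  cohort aged 65 in T.
- **Mean years with dementia** — over all subjects of that cohort
  (never-demented contributing zero), years lived demented truncated at age
  99; a conditional-on-demented variant is provided but is not the headline.
- **Exposure prevalence by age** — percent ever exposed among the alive.

## Uncertainty

Four inputs are resampled: the dementia incidence curve, RR(a), the
chronic-use incidence curve (log-normal: one shared N(0,1) deviate per sex
and curve scaled by the per-age SE of the log rate, preserving curve shape)
and the age-65 prevalence (logit-normal, SE derived from its 95% CI).  The
exposure relative risks and the mortality/population projections are fixed.
The joint sampling distribution of the inputs is not identifiable from
published summaries, so independence across curves is assumed; this is a
design choice, documented rather than hidden.

Each resampled bundle is pushed through the full two-pass projection at the
configured `n_per_cohort`, so the intervals include Monte Carlo sampling
noise as well as parameter uncertainty; intervals are empirical 2.5/97.5
percentiles (linear interpolation between order statistics), point estimates
come from the central unperturbed run, and scenario differences are computed
within runs (shared parameter draw and random numbers) before taking
percentiles.  The master seed spawns all streams deterministically via
`numpy` seed sequences; a run is reproducible from its manifest alone.

## Synthetic inputs and the oracle

The generator (`demproj.synthetic`) emulates the shape of a French-style
calibration: Gompertz dementia incidence and overall mortality (mortality
improving by a constant annual factor, default 0.988/year around 2015), a
declining-with-age incidence of chronic use, age-65 chronic-use prevalence
18.3% (women) / 11.2% (men), and a decreasing RR(a) of death for demented
subjects.  Default magnitudes were set once so that the 2040 burden is of
realistic order (prevalence rate ≈ 8–13% over 65–99, life expectancy
without dementia at 65 ≈ 22–26 years); they emulate plausible inputs and do
not reproduce any particular published estimate.  What passing tests on
synthetic bundles shows is that the machinery is correct under inputs of
realistic shape; it says nothing about the quality of any real country's
rate estimates, which the user must supply.  The generator is deterministic
given its spec; `noise_sd > 0` adds a smooth log-normal tilt per curve so
different seeds yield distinct bundles.

`dp_oracle` propagates the exact joint distribution over the five states
(non-demented/demented × unexposed/exposed, plus dead) with the same
one-year kernel as the engine — same event order, same probability
conversion — and returns exact expectations of every indicator.  It shares
the kernel's conventions by construction: it is the ground truth for the
stochastic machinery, not an independent model of the disease process.
Closed forms (death-only survival `(1−q)^k`, geometric life expectancy
`s/(1−s)`) validate the oracle itself.

## Numerical choices and degenerate inputs

- Intensity → probability via `1 − exp(−α)`: exact for a constant
  within-year intensity.
- Grids are annual and exact-match; no interpolation anywhere.
- Validation rejects NaN, negative and missing cells up front, naming the
  offending table and cell, so a validated bundle can always be projected
  without runtime lookup failures.
- Mean age at dementia is reported as missing (NaN) when a cohort has no
  case; life expectancy at ages with no qualifying subject is NaN in the
  indicator table.
- Resampled prevalences with a degenerate CI (width zero) are left at their
  central value.

## Problem sizes

Library defaults follow the method as specified (10,000 subjects per cohort,
100 resampling runs).  The packaged acceptance script and the test suite use
scaled-down sizes chosen as sensible demonstration defaults — 2,000 subjects
per cohort with 20 resampling runs for the end-to-end projection, and up to
200,000 subjects for single-cohort closed-form checks — which keep the whole
suite in the tens of seconds while leaving Monte Carlo error well inside the
tested tolerances.

## Known limitations

- The exposure effect is assumed causal, lifelong and homogeneous; no
  dose-response, no reversibility, no lag between chronic-use onset and risk
  change.
- Scenarios modify only the post-65 incidence of chronic use from the
  intervention year; the age-65 prevalence is left unchanged for all
  cohorts, including those turning 65 after the intervention.  An
  intervention that also prevented pre-65 chronic use would reduce that
  prevalence, so scenario effects here are conservative for later cohorts.
- No migration, no entry other than at age 65, follow-up capped at 105.
- Indicator conventions (whole-year counting, 99-year truncation) are exact
  for the discrete model but differ from continuous-time definitions by up
  to about half a year; comparisons with continuous-time results should
  keep that in mind.
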