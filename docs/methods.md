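# Methods

## Problem and model

The package estimates how adults aged 45+ move among three living
disability states — healthy, moderately limited, severely limited — and
death, from a three-wave biennial panel survey, and converts the fitted
transition schedule into health expectancies (HEs): the expected years
of remaining life spent in each state.

Disability states are coded from two activity-limitation items
(moderate and strenuous activities; response levels "not limited",
"limited a little", "limited a lot").  "Limited a lot" on either item
codes severe; otherwise "limited a little" on either codes moderate;
"not limited" on both codes healthy.  Respondents flagged by the
interviewer as too ill to respond are coded severe.  If neither item
qualifies and one is missing the state is missing, because a single
"not limited" answer cannot exclude limitation on the other item.  Two
alternative codings (healthy-vs-limited, and a three-level coding of
the five-level pain-interference item with cuts at "moderately" and
"extremely") support robustness analyses.

Annual transitions follow a discrete-time hazard model: for origin
state *i* and destination *j* ≠ *i*,

    logit-style linear predictor  eta_ij = b0_ij + b1_ij (age − 65) +
                                  b2_ij (age − 65)^2 + b3_ij male

combined through a multinomial logit per origin with baseline "remain
in *i*", so each row of the age/sex-specific transition matrix sums to
one by construction.  Death is absorbing.  Destinations never observed
from an origin are structural zeros.  A per-pair binary-logit mode
(stay probability by subtraction, renormalised) exists for sensitivity;
both modes are estimated by a damped Newton iteration on the exact
log-likelihood with analytic gradient and Hessian.  Quasi-separation
(any coefficient beyond 25 in absolute value) triggers a refit with a
1e-6 ridge penalty and is flagged in the diagnostics.

## Interval censoring and the midpoint convention

Exact transition and death dates are unknown; only the states at
attended waves (2 years apart) are observed.  Each interval is assumed
to contain at most one transition, placed at its midpoint: an interval
from state A at age *a* to state B at age *a*+2 contributes the annual
person-periods (*a*, A→B) and (*a*+1, B→B); death contributes only
(*a*, A→DEAD).  Longer gaps from skipped waves place the single
transition at the year nearest the interval midpoint with stayer-years
on either side (configurable to drop such intervals instead).

This convention deliberately ignores within-interval round trips
(e.g. healthy → moderate → healthy between waves).  When the underlying
process is a genuine annual-step Markov chain — which is exactly what
the synthetic generator simulates — the person-period likelihood is
therefore an approximation, and the fitted one-year model understates
flow intensities in and out of the transient states.  Measured on very
large synthetic cohorts (100,000 subjects, no attrition), the resulting
distortion is ~1–3% on total life expectancy and on the order of 10%
on the moderate/severe state-specific expectancies.  Total LE and the
broad age patterns are robust; state-specific occupancy of the more
transient states carries this approximation error, which is inherent to
midpoint-style estimation from interval-censored panels rather than to
the implementation.  Tests therefore verify the fitter itself against
annually observed data (where it is unbiased) and verify the end-to-end
pipeline at tolerances appropriate for each quantity.

Sample-inclusion rules: age 45+ at first usable interview; at least two
interviews, or one interview followed by death between waves (deaths
are ascertained even for non-respondents); records with missing sex,
age or coded state are dropped before pairing.

## Multistate life table

Cohorts of 100,000 synthetic individuals start at ages 45/55/65/75 with
a configurable joint sex × state distribution (by default the empirical
mix of respondents within ±2 years of the starting age) and are aged
forward annually until death or age 110.  Person-year crediting uses a
mid-cycle convention: stayers 1.0 year in their state, movers 0.5 + 0.5
between origin and destination, deaths 0.5 in the origin; anyone
reaching the cap is terminated with a 0.5-year credit.  A
start-state-full-year alternative is available behind a flag.  The
quadratic age predictor is never evaluated beyond 90 years (clamping,
both at fit and at evaluation time) because it is unsupported beyond
the observed age range and can turn over; with mortality bounded away
from zero at the clamped rates the truncation error at the 110 cap is
negligible (survival past 100 is already below 1e-3 at fitted rates).

`analytic_expectancies` propagates the expected state-occupancy vector
through the identical matrices with the identical crediting rules in
expectation, providing an exact (Monte-Carlo-free) oracle; microsim and
analytic values agree within sampling error by construction, which the
test suite checks at 4 Monte-Carlo standard errors using the per-person
variance from the same run.  HE additivity (active + moderate + severe
= total) holds to 1e-9 because the states partition the credited
person-years.

## Uncertainty

Confidence intervals come from a stratified nonparametric bootstrap:
subjects (all their waves) are redrawn with replacement within villages
to the village's original count, the entire pipeline (filters, periods,
refit, fresh microsimulation) is repeated, and the central 95% of the
replicate values (linear interpolation between order statistics) forms
the interval.  Intervals therefore reflect parameter and simulation
uncertainty together.  Default 499 replicates.  An alternative mode
resamples whole villages within regions as primary sampling units,
since survey-design phrasing of "stratification by village" is
ambiguous between the two; the default is subjects-within-villages.
Replicate failures (non-convergence) are dropped and counted; more than
10% failures raises an error.  Percentile intervals need not contain
the point estimate in skewed samples; only lower ≤ upper is guaranteed.

## Synthetic data generator

The generator emulates the study design the analysis assumes: ~2,500
subjects aged 45+ (entry ages discretised-exponential, mean excess 12
years) clustered in 121 villages over 3 regions, observed in 2006/2008/
2010; latent annual first-order Markov disability histories driven by
the same hazard model family; two-item responses realised so the coding
rules invert them exactly (healthy → both "not limited"; moderate →
exactly one "limited a little"; severe → one "limited a lot", or the
too-ill flag with probability 0.03); deaths between waves always
ascertained; wave non-response follows a logit with intercept 2.5 and
coefficients −0.02 per year of age over 45, −0.30 for moderate and
−0.60 for severe limitation, so attrition rises with age and
limitation as longitudinal ageing studies report.  Auxiliary items
(working for income, pain interference, life satisfaction) are drawn
independently per wave conditional on the state, with state gradients
matching the descriptive pattern of the study population (e.g. work
shares 0.38/0.34/0.26 across states).  A single seed drives
population, histories, attrition and items in that fixed order.

True transition coefficients default to values producing the
qualitative pattern reported for rural-African ageing cohorts: healthy
45-year-old men rarely (<5%/yr) leave health, recovery from limitation
is common at 45 and rare by 75, severe limitation is retentive, and
severe-state mortality is several-fold healthy-state mortality.  Under
these defaults 39% of fully observed subjects change state at least
once over the three waves — somewhat below the published cohort's 59%,
i.e. the generator is conservative about within-interval churn.

What the generator does not emulate: serial correlation in auxiliary
items, region-level heterogeneity beyond cluster labels, calendar-time
trends (transition rates are stationary by design), HIV status, and
duration-in-state dependence (the process is first-order Markov).
Passing end-to-end tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness
to their violation in real data.

## Scale choices in the test suite

Test and acceptance runs use problem sizes chosen so the full suite
completes comfortably on a single CPU: microsimulation oracles at
50,000–100,000 persons, end-to-end recovery at 5,000 subjects and 3
seeds, and the bootstrap coverage study at 200 synthetic datasets of
600 subjects with 99 replicates and 2,000-person microsimulations per
replicate.  Coverage datasets use 20 villages of ~30 subjects — the
published cohort's within-village size — rather than 121 villages of
~5, because stratified resampling within k-subject strata understates
variance by the factor (k−1)/k, a desk-scale artefact (20% at k=5)
that would measure the scaling rather than the method.  The coverage
target quantity is total life expectancy at 45 under the true
parameters and the generator's true initial mix.

## Known limitations

* Midpoint single-transition assumption: see above; state-specific HEs
  inherit an approximation error of order 10% under annual-chain truth.
* Attrition is handled by conditional ignorability given age, sex and
  current state; the generator's non-response actually depends on the
  state at the missed wave (the destination), so the synthetic design
  mildly violates ignorability, as real attrition plausibly does.  The
  induced bias at default attrition levels is small relative to
  sampling error at study scale.
* No design-based (sandwich) standard errors; clustering enters only
  through the bootstrap.
* No duration-dependent (semi-Markov) hazards; left-censoring of state
  durations makes them unidentifiable in a three-wave window.
* Initial cohort distributions for real analyses must be supplied via
  configuration; the synthetic pipeline uses the empirical mix near
  the starting age.
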