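# Methods

`postrepro` estimates how much of adult female life in a wild-primate-style
population is lived after reproductive cessation, from longitudinal records
with staggered observation windows. This note documents the estimators, the
simulator the tests run against, the numerical conventions, and the design
choices that were genuinely open.

## Data model

A cohort consists of females (estimated birth date, a symmetric birth-date
error in years, entry and exit dates, exit fate, entry mode) and parity
events (mother, offspring, birth date, offspring fate; twins are a single
event). Entry after birth — at habituation of the group or at immigration —
is left truncation: the female joins the risk set only at her entry age.
Exit by any route other than a recorded death (alive at study end,
disappeared, emigrated) is right censoring; a disappearance cannot be
distinguished from emigration, so treating it as death would bias mortality
upward. Ages are decimal years on a fixed 365.25-day year, which removes
leap-year ambiguity from age-class arithmetic.

## Demographic schedules

**Exposure and fecundity.** Age classes are one year, left-closed
`[x, x+1)`. Exposure is the summed overlap of each female's
`[entry_age, exit_age)` with the class; the headcount is the number of
females with positive overlap; births are parity events by mother age.
Age-specific fecundity is m(x) = births(x) / denominator(x), with two
denominators: `females_observed` (headcount; births per female observed at
that age — the default) and `female_years` (true exposure). The headcount
reading is the more literal one for observational schedules of this kind,
but it leaves a structural age trend in m(x): a female who dies or exits
mid-class counts as a full head against a partial year of exposure, so
late-age classes are systematically deflated. The exposure denominator is
free of that artifact and is used where exchangeability across age classes
matters (see the calibration test below). Classes with a zero denominator
have undefined m and are excluded from all cumulative-fecundity
computations.

**Survivorship.** l(x) is estimated nonparametrically with delayed-entry
risk sets: a female is at risk at age t if `entry < t <= exit`, deaths occur
at exit when the fate is death, and deaths precede censorings at tied ages
(the standard convention; the data give no reason to prefer another).
Two estimators are exposed:

* `product_limit` (default): l(x) = Π over death ages t ≤ x of (1 − d/n) —
  Kaplan–Meier with delayed entry;
* `breslow`: l(x) = exp(−Σ d/n) — the Nelson–Aalen cumulative hazard
  exponentiated, identical to the Breslow baseline survival of a
  covariate-free Cox model.

A proportional-hazards fit with no covariates estimates nothing beyond this
baseline, so the nonparametric estimators replace it outright; both are
provided because baseline-survival conventions differ across software.
Left truncation makes survival below the youngest entry age unidentifiable,
so l is anchored at 1 there. This anchoring is harmless for the target
statistic: rescaling l by any constant multiplies all person-year integrals
by that constant and cancels from every ratio (tested as a property).

The curve is stored as a right-continuous step function whose grid carries
both the pre- and post-jump value at each death age, so trapezoidal
integration over the grid is exact. T(x) = ∫ₓ^ω l(y) dy uses that grid with
linear interpolation at x; ω is the oldest observed age.

## Post-reproductive representation

PrR = T(M) / T(B), where B and M are the ages by which 5% and 95% of
cumulative population fecundity have occurred. Cumulative fecundity accrues
over age classes with weight l(x+½)·m(x) by default (realized cohort
fecundity — the share of births the actual survivorship schedule delivers
at each age), with raw m(x) as an option; both readings of "population
fecundity" are one flag apart because the phrase is genuinely ambiguous.
The crossing age is linearly interpolated within the crossing class, so a
single-class schedule yields B ≈ x+0.05 and M ≈ x+0.95 rather than a
degenerate B = M. PrR lies in [0, 1] by construction: T is nonincreasing
and B ≤ M.

**Permutation test.** The null of no age structure in fecundity is tested
by shuffling the multiset of defined m(x) values uniformly across their age
classes — survivorship held fixed, since it is not a function of fecundity —
and recomputing PrR per shuffle (10,000 iterations by default). "Shuffling"
is read literally as permutation without replacement. The p-value is the
add-one estimator (1 + #{null ≥ observed}) / (1 + N), which is never
exactly zero and keeps the test valid at Monte-Carlo resolution. The
permutation is vectorised (argsort of a uniform matrix), so 10,000
iterations cost milliseconds.

**Age-uncertainty simulation.** Birth-date estimation error is propagated
by, per iteration, drawing one offset per female uniformly from ± her age
error and shifting her entry age, exit age and the ages at her parity
events together — the uncertainty lives in the birth date, so all of a
female's ages share one offset (a flag restricts shifting to entry/exit
only). Schedules and survivorship are rebuilt per iteration and PrR and its
permutation p-value recorded; the summary is the mean and sample SD of the
PrR draws. With all errors zero the simulation returns the point estimate
in every iteration with SD exactly 0. Shifted entry ages are floored at
zero.

## Individual-level classification

Interbirth intervals (IBIs) are the gaps between consecutive parity events
of one mother, in continuous years. An interval is *successful* when the
earlier infant survived until the next birth (default rule); offspring with
no recorded death — censored as alive, disappeared or emigrated — count as
survived, and a fixed-years survival cutoff is available as the alternative
rule. Every excluded interval is logged with the infant's recorded death
time, so the filter is auditable. The classification threshold is the mean
plus two sample SDs (n−1) of successful IBIs. A female is flagged
post-reproductive when her years from last recorded birth to study exit
strictly exceed the threshold; exits of every kind count, because females
still alive at study end are exactly the ones a death-only rule would
discard. Females with no recorded birth are skipped — the criterion is
undefined without a last reproduction — but they still contribute exposure
and survivorship upstream.

## The synthetic cohort generator

The generator produces cohorts with the statistical structure the pipeline
assumes, so every stage is testable without field data. Per female, in a
fixed draw order from one seeded generator: a lifespan, a cessation age, a
reproductive schedule, a placement in calendar time, dispersal, and an age
error.

* **Mortality**: Gompertz hazard a·e^{b·age} with a = 0.015/y, b = 0.055/y,
  capped at a maximum age of 50 y — female gorillas rarely exceed 50 in the
  wild. These values put roughly 10% of survivorship at age 40 and are
  plausibility choices for a wild mountain-gorilla population, not
  estimates from any specific one. A piecewise-constant hazard is available
  for closed-form checks.
* **Reproduction**: first birth ~ Normal(10, 1.5²) y truncated at 8;
  successful IBIs ~ Normal(5.1, 1.3²) y truncated at 2. After an infant
  death (probability 0.25 per birth; death within ~half a year) the return
  to breeding is short, Normal(1.5, 0.75²) truncated at 0.5 y — this is
  what gives the "successful IBI" filter something to filter. Twins occur
  in 1% of parity events as a single event. An `exponential` IBI model
  replaces all waiting times (including to first birth, from the maturation
  minimum) with memoryless draws of the same mean, giving a constant birth
  hazard across adult ages for null calibration.
* **Cessation**: enabled by default at Normal(35, 2²) y — 35 y is around
  the oldest reproduction one expects to observe in such a population.
  Disabled, reproduction continues until death.
* **Observation**: a 1993–2025 study window. Females born during the study
  enter at birth with exact age; females alive at the study start enter at
  habituation (probability 0.5) or at a uniform immigration date.
  Emigration is a constant 0.02/y hazard after entry, recorded as
  "emigrated" or "disappeared" with equal probability; survival to the
  study end is censoring as "alive". Habituated and immigrant females get
  a uniform 0–4 y age error. Lives that would be observed for under a
  month are redrawn, since observational records only ever contain
  observed individuals. Parity events are recorded when they fall inside
  the observation window, plus pre-entry births back-identified from a
  surviving offspring still under 8 y at the mother's entry — mirroring how
  field studies reconstruct maternities from juveniles accompanying a
  female.
* **`complete` mode** bypasses the observation model: every female is
  followed birth-to-death with no censoring, truncation or age error. The
  ground truth `true_prr` runs the estimation pipeline on a 20,000-female
  complete cohort and is the recovery target for the estimators.

What the generator does **not** emulate: group structure and transfers
between habituated groups, male life histories, year effects or
environmental covariates in mortality and fertility, age-dependent infant
survival, and correlation between a female's age error and her entry age.
Passing tests therefore demonstrate correctness of the estimators under
the stated sampling structure, not robustness to every feature of real
field data.

## Verification design

The tests pin each stage to an independent oracle: exposure against
day-by-day accumulation; product-limit survivorship against the empirical
survival function on complete cohorts (exact) and against hand-enumerated
risk sets and `lifelines` with delayed entry on staggered toys; T(x)
against dense quadrature; quantile ages and PrR against a dense-grid
re-implementation; the Monte-Carlo permutation p against exhaustive
enumeration over all 120 permutations of a 5-class schedule.

Two system-level checks run at reduced, desk-scale sizes chosen to keep the
whole suite in the tens of seconds: type-I calibration (200 cohorts of 120
females, 1,000 permutations each) and parameter recovery (8 replicate
500-female cohorts per cessation age against a 20,000-female truth). The
calibration check uses the exposure denominator and the l·m weighting:
under a constant birth hazard that configuration makes the m(x) values
exchangeable across adult age classes, which is the premise the rejection
rate is being checked against; the headcount denominator's partial-year
artifact breaks that premise structurally, not through any defect of the
permutation machinery. The inner permutation count inside the uncertainty
simulation defaults to 10,000 in the library and is run at 1,000 in the
bundled end-to-end scripts.

## Known limitations

* With ~25 females the permutation test is underpowered: single synthetic
  study-scale cohorts frequently yield p-values well above 0.05 even when
  the generating process has genuine cessation.
* The headcount fecundity denominator is kept as the default for fidelity
  to observational practice despite its partial-year artifact; analyses
  that depend on cross-age comparability of m(x) should use
  `female_years`.
* Classification depends on recorded parities: a female whose cessation
  predates her entry and whose offspring were no longer identifiable at
  entry has no recorded birth and drops out of the individual-level count.
* The uncertainty simulation treats each female's age error as independent
  and uniform; correlated errors (e.g. a shared habituation date) are not
  modelled.
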