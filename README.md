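# postrepro

Demographic analysis of **post-reproductive lifespan** in longitudinal
records of individually known females — the kind of data produced by
decades-long field studies of wild primates, where females enter
observation at group habituation, at immigration, or at their own birth,
and leave it by death, disappearance, emigration, or the end of the study.
Entry after birth is left truncation; every exit other than a recorded
death is right censoring, and birth dates of females not born in the study
carry estimation errors of up to several years.

The package is for demographers and behavioural ecologists who want the
whole chain — schedules, statistic, inference, classification — as tested,
seedable code rather than a one-off script.

## What it computes

**Population level.** Post-reproductive representation

> PrR = T(M) / T(B),

where T(x) = ∫ₓ^ω l(y) dy is the expected person-years lived after age x
under the survivorship curve l, and B and M are the ages by which 5% and
95% of cumulative population fecundity m(x) have occurred. PrR is the
fraction of adult female person-years lived after reproduction has
effectively ceased: 0 when death follows the last birth immediately, 1 in
the limit where all adult years are post-reproductive. l(x) is estimated by
the product-limit (Kaplan–Meier) estimator with delayed-entry risk sets
(Breslow/Nelson–Aalen as an option); m(x) is births per female observed in
each one-year age class. Significance of PrR > 0 comes from shuffling the
fecundity values across age classes (survivorship fixed) and recomputing
the statistic, 10,000 times by default; robustness to age-estimation error
comes from re-running the whole pipeline with every female's ages shifted
by a draw from ± her birth-date error.

**Individual level.** A female is classified post-reproductive when her
years from last recorded birth to study exit exceed the mean plus two SDs
of *successful* interbirth intervals — intervals in which the earlier
infant survived to the next birth, so that quick conceptions after infant
deaths do not deflate the threshold.

**Simulator.** An individual-based life-history generator (Gompertz
mortality, truncated-normal interbirth intervals, optional reproductive
cessation, habituation/immigration entry, emigration and study-end
censoring, per-female age errors) produces cohorts with exactly this
structure, plus complete birth-to-death cohorts that yield the generator's
ground-truth PrR for recovery testing.

## Worked example

```python
from postrepro import SimConfig, generate_cohort
from postrepro.demography import exposure_schedule, fecundity_schedule, survivorship
from postrepro.prr import compute_prr, permutation_test, uncertainty_simulation
from postrepro.classify import successful_ibis, prl_threshold, classify_females

cohort = generate_cohort(SimConfig(), seed=11)   # 25 observed females
schedule = fecundity_schedule(exposure_schedule(cohort))
curve = survivorship(cohort)

point = compute_prr(curve, schedule)
perm = permutation_test(curve, schedule, 10_000, seed=2)
unc = uncertainty_simulation(cohort, n_iterations=1000, n_permutations=1000, seed=3)

stats = successful_ibis(cohort)
thr = prl_threshold(stats)
rows = classify_females(cohort, thr)
```

which prints, formatted:

```
females: 25 | parity events: 44
PrR = 0.154  (B = 9.8 y, M = 25.8 y)
permutation p = 0.0115  (10000 shuffles)
PrR under age uncertainty: 0.144 +/- 0.012 (SD)
successful IBIs: n = 23, mean = 5.1 y, SD = 1.3 y -> threshold = 7.7 y
post-reproductive females: 2 of 17 mothers
```

Reading: 5% of this cohort's fecundity falls before age 9.8 and 95% before
age 25.8; about 15% of the person-years lived past age B are lived past
age M, and fewer than 2% of fecundity shuffles reach a PrR that large, so
the age structure of reproduction is real rather than an artifact of the
schedule's spread. The estimate barely moves when every female's ages are
perturbed within her birth-date error. At the individual level, successful
interbirth intervals average 5.1 ± 1.3 y, so a female must exceed 7.7 y
past her last birth to be flagged; two of the seventeen mothers do.
Estimates at this cohort size are noisy by design — single 25-female
cohorts drawn from the same process range over roughly PrR 0.03–0.15.

The same pipeline runs from the shell, on simulated or real CSV tables:

```
postrepro simulate --seed 11 --out-prefix demo
postrepro all --females demo_females.csv --births demo_births.csv --out-dir run/
postrepro classify --females demo_females.csv --births demo_births.csv
```

`postrepro all` writes the schedules, survivorship curve, null and
uncertainty distributions, per-female classification table, a JSON report
and a manifest (seeds, options, version) under the run directory. Input
CSVs follow the column contract in `postrepro.data_io`.

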