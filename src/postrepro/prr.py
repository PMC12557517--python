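"""Post-reproductive representation (PrR) and its inference.

PrR measures, at the population level, the share of adult female
person-years lived after reproduction has effectively ceased:

    PrR = T(M) / T(B)

where B and M are the ages by which 5% and 95% of cumulative population
fecundity have occurred and T(x) is the expected person-years lived after
age x, obtained by integrating the survivorship curve.  PrR = 0 means no
survival past the reproductive span; PrR = 1 would mean all adult years are
post-reproductive.

Two inference procedures accompany the point estimate:

* a permutation test that shuffles the age-specific fecundity values m(x)
  across age classes (survivorship held fixed) and asks how often a shuffled
  schedule yields a PrR at least as large as the observed one;
* an age-uncertainty simulation that redraws every female's birth date
  within her estimation error, shifting all her ages by one common offset,
  and rebuilds the whole pipeline per draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Cohort
from .demography import (
    AgeObservations,
    AgeSchedule,
    SurvivorshipCurve,
    exposure_schedule,
    fecundity_schedule,
    person_years_after,
    survivorship,
)

__all__ = [
    "PrRResult",
    "PermutationResult",
    "UncertaintyResult",
    "UndefinedStatisticError",
    "fecundity_quantile_age",
    "compute_prr",
    "permutation_test",
    "uncertainty_simulation",
]

WEIGHTINGS = ("l_times_m", "m_only")


class UndefinedStatisticError(ValueError):
    """PrR is undefined for this input (no fecundity or no person-years)."""


@dataclass
class PrRResult:
    prr: float
    age_B: float  # age at 5% cumulative fecundity
    age_M: float  # age at 95% cumulative fecundity
    T_B: float
    T_M: float
    weighting: str

    def as_dict(self) -> dict:
        return {
            "prr": self.prr,
            "age_B": self.age_B,
            "age_M": self.age_M,
            "T_B": self.T_B,
            "T_M": self.T_M,
            "weighting": self.weighting,
        }


@dataclass
class PermutationResult:
    observed_prr: float
    null_prr: np.ndarray
    n_iterations: int
    p_value: float
    seed: int


@dataclass
class UncertaintyResult:
    prr_values: np.ndarray
    p_values: np.ndarray
    mean_prr: float
    sd_prr: float
    n_iterations: int
    seed: int


# ---------------------------------------------------------------------------
# internals: fecundity weights, T(x) interpolator, vectorised quantile ages


def _class_weights(
    curve: SurvivorshipCurve, schedule: AgeSchedule, weighting: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(class lower bounds, m values, survivorship factors) over the classes
    where m is defined.  The survivorship factor is l at the class midpoint
    (1 for ``m_only``)."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    defined = schedule.defined
    ages = schedule.ages[defined].astype(float)
    m = schedule.fecundity[defined]
    if len(m) == 0 or not np.any(m > 0):
        raise UndefinedStatisticError("no age class with positive fecundity")
    if weighting == "l_times_m":
        lfac = curve.evaluate(ages + 0.5)
    else:
        lfac = np.ones_like(ages)
    return ages, m, lfac


def _t_interpolator(curve: SurvivorshipCurve):
    """Return T(x) as a fast callable; T is continuous and piecewise linear
    on the step curve's grid.  Ages below the baseline extend with l ≡ 1
    (no mortality is identified there); ages beyond ω give 0."""
    grid, l = curve.age_grid, curve.l
    seg = 0.5 * (l[1:] + l[:-1]) * np.diff(grid)
    tail = np.concatenate((np.cumsum(seg[::-1])[::-1], [0.0]))

    def T(x):
        x = np.asarray(x, dtype=float)
        base = np.interp(x, grid, tail)
        below = x < grid[0]
        return np.where(below, tail[0] + l[0] * (grid[0] - x), base)

    return T


def _quantile_ages_matrix(
    ages: np.ndarray, weights: np.ndarray, q: float
) -> np.ndarray:
    """Age at which cumulative weight crosses fraction q, linearly
    interpolated within the crossing one-year class.  ``weights`` has one
    row per schedule (vectorised over permutations)."""
    cum = np.cumsum(weights, axis=1)
    total = cum[:, -1]
    target = q * total
    # first class where the running sum reaches the target
    j = np.sum(cum < target[:, None] - 1e-15, axis=1)
    j = np.minimum(j, weights.shape[1] - 1)
    rows = np.arange(weights.shape[0])
    prev = np.where(j > 0, cum[rows, np.maximum(j - 1, 0)], 0.0)
    w = weights[rows, j]
    frac = np.where(w > 0, (target - prev) / np.where(w > 0, w, 1.0), 0.0)
    return ages[j] + np.clip(frac, 0.0, 1.0)


def fecundity_quantile_age(
    curve: SurvivorshipCurve,
    schedule: AgeSchedule,
    q: float,
    weighting: str = "l_times_m",
) -> float:
    """Age by which a fraction *q* of cumulative population fecundity has
    occurred.

    Cumulative fecundity accrues over one-year age classes with weight
    m(x) (``m_only``) or l(x)·m(x) (``l_times_m``, realized cohort
    fecundity); the crossing age is linearly interpolated within the class.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie in (0, 1), got {q}")
    ages, m, lfac = _class_weights(curve, schedule, weighting)
    w = (m * lfac)[None, :]
    return float(_quantile_ages_matrix(ages, w, q)[0])


def compute_prr(
    curve: SurvivorshipCurve,
    schedule: AgeSchedule,
    weighting: str = "l_times_m",
) -> PrRResult:
    """PrR = T(M)/T(B) with B, M the 5% and 95% cumulative-fecundity ages."""
    age_B = fecundity_quantile_age(curve, schedule, 0.05, weighting)
    age_M = fecundity_quantile_age(curve, schedule, 0.95, weighting)
    T = _t_interpolator(curve)
    T_B = float(T(age_B))
    T_M = float(T(age_M))
    if T_B <= 0:
        raise UndefinedStatisticError(
            "no adult person-years after the 5% fecundity age (T_B = 0)"
        )
    return PrRResult(
        prr=T_M / T_B, age_B=age_B, age_M=age_M, T_B=T_B, T_M=T_M,
        weighting=weighting,
    )


def _null_prr_values(
    curve: SurvivorshipCurve,
    schedule: AgeSchedule,
    n_iterations: int,
    rng: np.random.Generator,
    weighting: str,
) -> np.ndarray:
    ages, m, lfac = _class_weights(curve, schedule, weighting)
    k = len(m)
    if k < 2:
        raise UndefinedStatisticError(
            "fewer than 2 age classes with defined fecundity; nothing to permute"
        )
    T = _t_interpolator(curve)
    order = np.argsort(rng.random((n_iterations, k)), axis=1)
    W = m[order] * lfac[None, :]
    age_B = _quantile_ages_matrix(ages, W, 0.05)
    age_M = _quantile_ages_matrix(ages, W, 0.95)
    T_B = T(age_B)
    T_M = T(age_M)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(T_B > 0, T_M / np.where(T_B > 0, T_B, 1.0), 0.0)
    return out


def permutation_test(
    curve: SurvivorshipCurve,
    schedule: AgeSchedule,
    n_iterations: int = 10_000,
    seed: int = 0,
    weighting: str = "l_times_m",
) -> PermutationResult:
    """Permutation significance of PrR > 0.

    Each iteration permutes the m(x) values uniformly at random across the
    age classes where m is defined, holds survivorship fixed, and recomputes
    PrR.  The p-value uses the add-one estimator
    (1 + #{null ≥ observed}) / (1 + n), so it is never exactly zero.
    """
    observed = compute_prr(curve, schedule, weighting).prr
    rng = np.random.default_rng(seed)
    null = _null_prr_values(curve, schedule, n_iterations, rng, weighting)
    exceed = int(np.sum(null >= observed - 1e-12))
    p = (1 + exceed) / (1 + n_iterations)
    return PermutationResult(
        observed_prr=observed,
        null_prr=null,
        n_iterations=n_iterations,
        p_value=p,
        seed=seed,
    )


def uncertainty_simulation(
    cohort: Cohort,
    n_iterations: int = 1_000,
    n_permutations: int = 10_000,
    seed: int = 0,
    weighting: str = "l_times_m",
    denominator: str = "females_observed",
    method: str = "product_limit",
    shift_birth_events: bool = True,
) -> UncertaintyResult:
    """Propagate birth-date estimation error into PrR and its p-value.

    Per iteration, each female receives one offset drawn uniformly from
    ±her age error; her entry age, exit age and (by default) the ages at her
    parity events shift together, since the uncertainty is in her birth
    date.  Schedules and survivorship are rebuilt and PrR plus its
    permutation p-value recorded.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    base = AgeObservations.from_cohort(cohort)
    errors = np.array([f.age_error for f in cohort.females], dtype=float)
    rng = np.random.default_rng(seed)
    prr_values = np.empty(n_iterations)
    p_values = np.empty(n_iterations)
    for i in range(n_iterations):
        offsets = rng.uniform(-errors, errors) if np.any(errors > 0) else np.zeros_like(errors)
        obs = base.shifted(offsets, shift_birth_events=shift_birth_events)
        schedule = fecundity_schedule(exposure_schedule(obs), denominator)
        curve = survivorship(obs, method=method)
        prr_values[i] = compute_prr(curve, schedule, weighting).prr
        null = _null_prr_values(curve, schedule, n_permutations, rng, weighting)
        p_values[i] = (1 + int(np.sum(null >= prr_values[i] - 1e-12))) / (
            1 + n_permutations
        )
    if n_iterations > 1 and np.any(prr_values != prr_values[0]):
        sd = float(np.std(prr_values, ddof=1))
    else:
        sd = 0.0  # degenerate case (e.g. all age errors zero): exactly 0
    return UncertaintyResult(
        prr_values=prr_values,
        p_values=p_values,
        mean_prr=float(np.mean(prr_values)),
        sd_prr=sd,
        n_iterations=n_iterations,
        seed=seed,
    )
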