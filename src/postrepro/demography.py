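"""Age-indexed demographic schedules from staggered-entry observation data.

The cohort is projected onto an age axis: each female is at risk from her
entry age to her exit age, deaths are exits with fate ``died``, and all other
exits are right-censoring.  Three estimands follow:

* exposure and headcount per one-year age class ``[x, x+1)``;
* age-specific fecundity m(x), births per female observed in the class;
* survivorship l(x) with delayed entry, by the product-limit estimator
  (default) or the Breslow / Nelson–Aalen exponential form — the latter
  matches the baseline survival of a covariate-free Cox fit.

Because survival below the youngest entry age is unidentified under left
truncation, l is anchored at 1 at the youngest entry age.  All ratios of
person-years T(x) = ∫ l — and hence the post-reproductive representation
built on them — are invariant to that anchoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd

from .data_io import Cohort, ExitFate

__all__ = [
    "AgeObservations",
    "AgeSchedule",
    "SurvivorshipCurve",
    "exposure_schedule",
    "fecundity_schedule",
    "restrict_schedule",
    "survivorship",
    "person_years_after",
]


@dataclass
class AgeObservations:
    """Cohort reduced to the age axis: per-female risk windows plus the
    mother ages at every parity event.

    ``mother_index`` maps each birth to its mother's row, so a per-female
    age offset (birth-date uncertainty) can shift a female's window and her
    parity ages together.
    """

    entry: np.ndarray  # entry ages, years
    exit: np.ndarray  # exit ages, years
    died: np.ndarray  # bool, exit is a death
    birth_ages: np.ndarray  # mother age at each parity event
    mother_index: np.ndarray  # int, row of the mother for each parity event

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "AgeObservations":
        idx = {f.female_id: i for i, f in enumerate(cohort.females)}
        entry = np.array([f.entry_age for f in cohort.females], dtype=float)
        exit_ = np.array([f.exit_age for f in cohort.females], dtype=float)
        died = np.array(
            [f.exit_fate is ExitFate.DIED for f in cohort.females], dtype=bool
        )
        mother_index = np.array(
            [idx[b.mother_id] for b in cohort.births], dtype=int
        )
        birth_ages = np.array(
            [
                (b.birth_date - cohort.females[idx[b.mother_id]].birth_date).days
                / 365.25
                for b in cohort.births
            ],
            dtype=float,
        )
        return cls(entry, exit_, died, birth_ages, mother_index)

    def shifted(self, offsets: np.ndarray, shift_birth_events: bool = True) -> "AgeObservations":
        """All ages of female i shifted by ``offsets[i]`` (one birth-date
        offset per female)."""
        offsets = np.asarray(offsets, dtype=float)
        birth_ages = self.birth_ages
        if shift_birth_events and len(birth_ages):
            birth_ages = birth_ages + offsets[self.mother_index]
        return AgeObservations(
            entry=np.maximum(self.entry + offsets, 0.0),
            exit=np.maximum(self.exit + offsets, 0.0),
            died=self.died,
            birth_ages=birth_ages,
            mother_index=self.mother_index,
        )


def _as_obs(data: Union[Cohort, AgeObservations]) -> AgeObservations:
    if isinstance(data, AgeObservations):
        return data
    return AgeObservations.from_cohort(data)


@dataclass
class AgeSchedule:
    """Per one-year age class ``[x, x+1)``: exposure, headcount, births, m(x).

    ``fecundity`` is NaN until :func:`fecundity_schedule` fills it; classes
    whose denominator is zero stay NaN (undefined), and are excluded from
    cumulative-fecundity computations and from permutation.
    """

    ages: np.ndarray  # integer class lower bounds
    exposure: np.ndarray  # female-years in the class
    females_observed: np.ndarray  # headcount with positive overlap
    births: np.ndarray  # parity events with mother age in the class
    fecundity: np.ndarray  # m(x); NaN where undefined
    denominator: str = ""

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.fecundity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "exposure": self.exposure,
                "females_observed": self.females_observed,
                "births": self.births,
                "fecundity": self.fecundity,
            }
        )


def exposure_schedule(data: Union[Cohort, AgeObservations]) -> AgeSchedule:
    """Tabulate female-years, headcount and parity events per age class.

    A female observed over ``[entry_age, exit_age)`` contributes to class x
    the length of the overlap with ``[x, x+1)``; she is counted in the
    headcount of every class with positive overlap.
    """
    obs = _as_obs(data)
    if len(obs.entry) == 0:
        empty = np.array([], dtype=float)
        return AgeSchedule(
            ages=np.array([], dtype=int),
            exposure=empty,
            females_observed=np.array([], dtype=int),
            births=np.array([], dtype=int),
            fecundity=empty,
        )
    lo_edge = obs.entry.min()
    hi_edge = obs.exit.max()
    if len(obs.birth_ages):
        # parity events outside any observation window (e.g. known from
        # genetic identification of offspring) still get a class; fecundity
        # stays undefined there because the denominator is zero
        lo_edge = min(lo_edge, obs.birth_ages.min())
        hi_edge = max(hi_edge, obs.birth_ages.max() + 1e-9)
    lo = int(np.floor(lo_edge))
    hi = int(np.ceil(hi_edge))
    hi = max(hi, lo + 1)
    ages = np.arange(lo, hi, dtype=int)

    left = ages[None, :].astype(float)
    overlap = np.clip(
        np.minimum(obs.exit[:, None], left + 1.0)
        - np.maximum(obs.entry[:, None], left),
        0.0,
        None,
    )
    exposure = overlap.sum(axis=0)
    females_observed = (overlap > 0).sum(axis=0)

    births = np.zeros(len(ages), dtype=int)
    if len(obs.birth_ages):
        cls = np.floor(obs.birth_ages).astype(int)
        for c in cls:
            births[c - lo] += 1

    return AgeSchedule(
        ages=ages,
        exposure=exposure,
        females_observed=females_observed.astype(int),
        births=births,
        fecundity=np.full(len(ages), np.nan),
    )


def fecundity_schedule(
    schedule: AgeSchedule, denominator: str = "females_observed"
) -> AgeSchedule:
    """Fill m(x) = births(x) / denominator(x).

    ``denominator`` is ``"females_observed"`` (headcount — births per female
    observed at that age) or ``"female_years"`` (true exposure).  Classes
    with a zero denominator are left undefined (NaN).
    """
    if denominator not in ("females_observed", "female_years"):
        raise ValueError(f"unknown denominator {denominator!r}")
    denom = (
        schedule.females_observed.astype(float)
        if denominator == "females_observed"
        else schedule.exposure
    )
    m = np.full(len(schedule.ages), np.nan)
    ok = denom > 0
    m[ok] = schedule.births[ok] / denom[ok]
    return replace(schedule, fecundity=m, denominator=denominator)


def restrict_schedule(schedule: AgeSchedule, min_age: float = -np.inf,
                      max_age: float = np.inf) -> AgeSchedule:
    """Subset of age classes with ``min_age <= x < max_age`` (e.g. to limit
    the analysis to adult ages)."""
    keep = (schedule.ages >= min_age) & (schedule.ages < max_age)
    return AgeSchedule(
        ages=schedule.ages[keep],
        exposure=schedule.exposure[keep],
        females_observed=schedule.females_observed[keep],
        births=schedule.births[keep],
        fecundity=schedule.fecundity[keep],
        denominator=schedule.denominator,
    )


@dataclass
class SurvivorshipCurve:
    """l(x) on an age grid; a right-continuous step function.

    Each drop is represented by a duplicated grid age carrying the pre- and
    post-jump value, so trapezoidal integration over the grid is exact and
    linear interpolation between grid points reproduces the step function.
    """

    age_grid: np.ndarray
    l: np.ndarray
    baseline_age: float

    def evaluate(self, x) -> np.ndarray:
        """Right-continuous evaluation; l = 1 at and below the baseline."""
        x = np.asarray(x, dtype=float)
        idx = np.clip(
            np.searchsorted(self.age_grid, x, side="right") - 1,
            0,
            len(self.age_grid) - 1,
        )
        out = self.l[idx]
        # below the baseline no mortality is identified: extend with the
        # anchor value (1 for an estimated curve, scaled under rescaling)
        return np.where(x <= self.baseline_age, self.l[0], out)

    def rescaled(self, factor: float) -> "SurvivorshipCurve":
        return SurvivorshipCurve(self.age_grid, self.l * factor, self.baseline_age)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age_grid, "survivorship": self.l})


def survivorship(
    data: Union[Cohort, AgeObservations], method: str = "product_limit"
) -> SurvivorshipCurve:
    """Nonparametric survivorship under delayed entry and right censoring.

    A female is at risk at age t if ``entry < t <= exit``; deaths occur at
    exit age when the exit fate is death.  At tied ages deaths are processed
    before censorings (censored females remain in the risk set).

    ``product_limit``: l(x) = Π_{deaths t ≤ x} (1 − d(t)/n(t)) — the
    Kaplan–Meier form.  ``breslow``: l(x) = exp(−Σ d(t)/n(t)) — the
    Nelson–Aalen cumulative hazard exponentiated, i.e. the Breslow baseline
    survival of a null Cox model.
    """
    if method not in ("product_limit", "breslow"):
        raise ValueError(f"unknown method {method!r}")
    obs = _as_obs(data)
    n = len(obs.entry)
    if n == 0:
        raise ValueError("empty cohort: survivorship undefined")
    if np.all(obs.exit <= obs.entry):
        raise ValueError("all individuals at risk for zero time")

    baseline = float(obs.entry.min())
    omega = float(obs.exit.max())

    death_ages = np.unique(obs.exit[obs.died])
    grid = [baseline]
    values = [1.0]
    surv = 1.0
    for t in death_ages:
        at_risk = int(np.sum((obs.entry < t) & (t <= obs.exit)))
        d = int(np.sum(obs.died & (obs.exit == t)))
        if at_risk == 0:
            continue  # death at an age with no identified risk set
        grid.append(t)
        values.append(surv)
        if method == "product_limit":
            surv *= 1.0 - d / at_risk
        else:
            surv *= np.exp(-d / at_risk)
        grid.append(t)
        values.append(surv)
    if omega > grid[-1]:
        grid.append(omega)
        values.append(surv)
    return SurvivorshipCurve(
        age_grid=np.array(grid, dtype=float),
        l=np.array(values, dtype=float),
        baseline_age=baseline,
    )


def person_years_after(curve: SurvivorshipCurve, x: float) -> float:
    """T(x) = ∫ₓ^ω l(y) dy on the curve's grid (trapezoidal; exact for the
    step representation).  ``x`` must lie within [baseline_age, ω]."""
    grid, l = curve.age_grid, curve.l
    omega = grid[-1]
    if x < curve.baseline_age - 1e-12 or x > omega + 1e-12:
        raise ValueError(
            f"x={x} outside survivorship grid [{curve.baseline_age}, {omega}]"
        )
    x = min(max(x, grid[0]), omega)
    keep = grid >= x
    gx = np.concatenate(([x], grid[keep]))
    lx = np.concatenate(([curve.evaluate(x)], l[keep]))
    return float(np.trapezoid(lx, gx))
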