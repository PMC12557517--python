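"""Individual-level post-reproductive classification.

A female counts as post-reproductive when the years she has lived past her
last recorded birth exceed the mean plus two standard deviations of
*successful* interbirth intervals (IBIs) in the population — intervals in
which the earlier infant survived, so that short return-to-breeding gaps
after infant deaths do not deflate the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import Cohort, ExitFate, age_at

__all__ = [
    "IBIStats",
    "ExcludedInterval",
    "FemalePRL",
    "successful_ibis",
    "prl_threshold",
    "classify_females",
]


@dataclass
class ExcludedInterval:
    """Audit record for an interval dropped by the success filter."""

    mother_id: str
    interval_years: float
    infant_id: str
    infant_death_years_after_birth: float


@dataclass
class IBIStats:
    """Successful interbirth intervals with their mean, SD and the
    mean + 2·SD threshold (sample SD, n−1 denominator)."""

    intervals: np.ndarray
    mean: float
    sd: float
    threshold: float
    excluded: list[ExcludedInterval] = field(default_factory=list)

    @classmethod
    def from_intervals(
        cls, intervals, excluded: Optional[list[ExcludedInterval]] = None
    ) -> "IBIStats":
        arr = np.asarray(intervals, dtype=float)
        if len(arr) < 1:
            raise ValueError("no successful intervals")
        mean = float(np.mean(arr))
        # SD (and hence the threshold) needs >= 2 intervals
        sd = float(np.std(arr, ddof=1)) if len(arr) >= 2 else float("nan")
        return cls(
            intervals=arr,
            mean=mean,
            sd=sd,
            threshold=mean + 2.0 * sd,
            excluded=excluded or [],
        )

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "IBIStats":
        """Stats object from published moments, when raw intervals are not
        available."""
        return cls(
            intervals=np.array([]), mean=float(mean), sd=float(sd),
            threshold=float(mean) + 2.0 * float(sd),
        )


@dataclass
class FemalePRL:
    """Per-female post-reproductive summary (one row of the classification
    table)."""

    female_id: str
    age_last_birth: float
    age_exit: float
    years_since_last_birth: float
    is_postreproductive: bool
    age_error: float


def successful_ibis(
    cohort: Cohort,
    success_rule: str = "next_birth",
    fixed_years: Optional[float] = None,
) -> IBIStats:
    """Successful interbirth intervals across all mothers with ≥ 2 births.

    Intervals run between consecutive parity events of one mother (twins are
    one event).  ``success_rule``:

    * ``"next_birth"`` (default): the earlier infant must have survived
      until the subsequent birth; an infant with a recorded death before
      that birth excludes the interval.  Censored offspring (alive,
      disappeared, emigrated) count as survived.
    * ``"fixed_years"``: the earlier infant must have survived at least
      ``fixed_years`` years.

    Returns the interval collection with mean, SD, mean + 2·SD threshold
    and an audit list of excluded intervals.
    """
    if success_rule not in ("next_birth", "fixed_years"):
        raise ValueError(f"unknown success_rule {success_rule!r}")
    if success_rule == "fixed_years" and (fixed_years is None or fixed_years <= 0):
        raise ValueError("fixed_years rule requires a positive fixed_years")

    intervals: list[float] = []
    excluded: list[ExcludedInterval] = []
    for female in cohort.females:
        births = cohort.births_of(female.female_id)
        if len(births) < 2:
            continue
        for earlier, later in zip(births[:-1], births[1:]):
            gap = (later.birth_date - earlier.birth_date).days / 365.25
            survived = earlier.offspring_survived_years
            if survived is None:  # no recorded death: treated as survived
                ok = True
            elif success_rule == "next_birth":
                ok = survived >= gap
            else:
                ok = survived >= fixed_years
            if ok:
                intervals.append(gap)
            else:
                excluded.append(
                    ExcludedInterval(
                        mother_id=female.female_id,
                        interval_years=gap,
                        infant_id=earlier.offspring_id,
                        infant_death_years_after_birth=survived,
                    )
                )
    if not intervals:
        raise ValueError("no successful interbirth intervals in cohort")
    return IBIStats.from_intervals(intervals, excluded=excluded)


def prl_threshold(stats: IBIStats) -> float:
    """Post-reproductive threshold: mean + 2·SD of successful IBIs.

    Recomputed from the raw intervals when present (sample SD, n−1);
    otherwise taken from the stored moments.
    """
    if len(stats.intervals) == 1:
        raise ValueError("fewer than 2 successful intervals; SD undefined")
    if len(stats.intervals) >= 2:
        mean = float(np.mean(stats.intervals))
        sd = float(np.std(stats.intervals, ddof=1))
        return mean + 2.0 * sd
    return stats.mean + 2.0 * stats.sd


def classify_females(cohort: Cohort, threshold: float) -> list[FemalePRL]:
    """Flag each mother as post-reproductive iff her years since last birth
    exceed *threshold* (strict inequality).

    Years since last birth run from the last recorded parity event to study
    exit regardless of exit fate, so females still alive (censored) at study
    end are classified on their observed span.  Females with no recorded
    birth are skipped: the criterion is undefined without a last
    reproduction.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    out: list[FemalePRL] = []
    for female in cohort.females:
        births = cohort.births_of(female.female_id)
        if not births:
            continue
        age_last = age_at(female, births[-1].birth_date)
        age_exit = female.exit_age
        span = age_exit - age_last
        out.append(
            FemalePRL(
                female_id=female.female_id,
                age_last_birth=age_last,
                age_exit=age_exit,
                years_since_last_birth=span,
                is_postreproductive=span > threshold,
                age_error=female.age_error,
            )
        )
    return out


def classification_frame(rows: list[FemalePRL]) -> pd.DataFrame:
    """Tidy per-female table (one row per classified female)."""
    return pd.DataFrame(
        [
            {
                "female_id": r.female_id,
                "age_last_birth": r.age_last_birth,
                "age_exit": r.age_exit,
                "years_since_last_birth": r.years_since_last_birth,
                "is_postreproductive": r.is_postreproductive,
                "age_error": r.age_error,
            }
            for r in rows
        ],
        columns=[
            "female_id",
            "age_last_birth",
            "age_exit",
            "years_since_last_birth",
            "is_postreproductive",
            "age_error",
        ],
    )
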