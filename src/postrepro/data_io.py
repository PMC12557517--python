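"""Cohort data model and CSV input/output.

Longitudinal life-history records of individually known females observed in
staggered windows: a female enters observation at habituation of her group,
at immigration, or at her own birth, and leaves it at death, disappearance,
emigration, or the end of the study.  Entry after birth produces left
truncation; any exit other than death is right censoring.

Dates are ISO-8601 calendar dates; ages are decimal years on a fixed
365.25-day year, which keeps age arithmetic leap-year free.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "MIN_MATURATION_YEARS",
    "ExitFate",
    "EntryMode",
    "FemaleRecord",
    "BirthEvent",
    "Cohort",
    "CohortValidationError",
    "age_at",
    "read_cohort",
    "write_cohort",
]

DAYS_PER_YEAR = 365.25

#: Youngest biologically admissible age at a parity event.  Wild gorilla
#: females do not give birth before roughly age eight; six years leaves slack
#: for birth-date estimation error while still catching data-entry mistakes.
MIN_MATURATION_YEARS = 6.0

FEMALES_COLUMNS = [
    "female_id",
    "birth_date",
    "age_error_years",
    "entry_date",
    "exit_date",
    "exit_fate",
    "entry_mode",
]

BIRTHS_COLUMNS = [
    "mother_id",
    "offspring_id",
    "birth_date",
    "offspring_exit_date",
    "offspring_exit_fate",
    "is_twin_event",
]


class CohortValidationError(ValueError):
    """A cohort table violates the data contract; message names the row."""


class ExitFate(str, enum.Enum):
    """How a female (or offspring) left observation.

    Only ``DIED`` is a death event for survivorship; ``ALIVE``,
    ``DISAPPEARED`` and ``EMIGRATED`` are right-censoring, since a
    disappearance cannot be distinguished from emigration to an
    unhabituated group.
    """

    ALIVE = "alive"
    DIED = "died"
    DISAPPEARED = "disappeared"
    EMIGRATED = "emigrated"


class EntryMode(str, enum.Enum):
    HABITUATION = "habituation"
    IMMIGRATION = "immigration"
    BORN_IN_STUDY = "born_in_study"


def age_at(female: "FemaleRecord", date: _dt.date) -> float:
    """Age of *female* on *date*, in decimal years.

    Raises ``ValueError`` if *date* precedes the (estimated) birth date.
    """
    days = (date - female.birth_date).days
    if days < 0:
        raise ValueError(
            f"date {date} precedes birth date {female.birth_date} "
            f"of female {female.female_id!r}"
        )
    return days / DAYS_PER_YEAR


@dataclass(frozen=True)
class FemaleRecord:
    """One observed female: estimated birth date, observation window, fate."""

    female_id: str
    birth_date: _dt.date
    age_error: float  # half-width of birth-date uncertainty, years; 0 = exact
    entry_date: _dt.date
    exit_date: _dt.date
    exit_fate: ExitFate
    entry_mode: EntryMode

    @property
    def entry_age(self) -> float:
        return age_at(self, self.entry_date)

    @property
    def exit_age(self) -> float:
        return age_at(self, self.exit_date)

    def validate(self) -> None:
        fid = self.female_id
        if not fid:
            raise CohortValidationError("female with empty female_id")
        if self.age_error < 0:
            raise CohortValidationError(
                f"female {fid!r}: negative age_error {self.age_error}"
            )
        if not (self.birth_date <= self.entry_date):
            raise CohortValidationError(
                f"female {fid!r}: entry_date {self.entry_date} precedes "
                f"birth_date {self.birth_date}"
            )
        if not (self.entry_date <= self.exit_date):
            raise CohortValidationError(
                f"female {fid!r}: exit_date {self.exit_date} precedes "
                f"entry_date {self.entry_date}"
            )
        if self.entry_mode is EntryMode.BORN_IN_STUDY:
            if self.age_error != 0:
                raise CohortValidationError(
                    f"female {fid!r}: born in study but age_error "
                    f"{self.age_error} != 0"
                )
            if self.entry_date != self.birth_date:
                raise CohortValidationError(
                    f"female {fid!r}: born in study but entry_date "
                    f"{self.entry_date} != birth_date {self.birth_date}"
                )


@dataclass(frozen=True)
class BirthEvent:
    """One parity event.  Twins are a single event with ``is_twin_event``."""

    mother_id: str
    offspring_id: str
    birth_date: _dt.date
    offspring_exit_date: Optional[_dt.date]  # None = alive at study end
    offspring_exit_fate: ExitFate
    is_twin_event: bool = False

    @property
    def offspring_survived_years(self) -> Optional[float]:
        """Known offspring survival in years, or None if open-ended.

        Only a recorded death bounds survival from above; censored offspring
        (alive, disappeared, emigrated) are open-ended.
        """
        if self.offspring_exit_fate is not ExitFate.DIED:
            return None
        if self.offspring_exit_date is None:
            return None
        return (self.offspring_exit_date - self.birth_date).days / DAYS_PER_YEAR


@dataclass
class Cohort:
    """A set of females plus their parity events, validated as a whole."""

    females: list[FemaleRecord] = field(default_factory=list)
    births: list[BirthEvent] = field(default_factory=list)

    @property
    def n_females(self) -> int:
        return len(self.females)

    @property
    def n_births(self) -> int:
        return len(self.births)

    def female(self, female_id: str) -> FemaleRecord:
        for f in self.females:
            if f.female_id == female_id:
                return f
        raise KeyError(female_id)

    def births_of(self, female_id: str) -> list[BirthEvent]:
        out = [b for b in self.births if b.mother_id == female_id]
        out.sort(key=lambda b: b.birth_date)
        return out

    def validate(self) -> "Cohort":
        seen: set[str] = set()
        for f in self.females:
            f.validate()
            if f.female_id in seen:
                raise CohortValidationError(
                    f"duplicate female_id {f.female_id!r}"
                )
            seen.add(f.female_id)
        by_id = {f.female_id: f for f in self.females}
        for i, b in enumerate(self.births):
            mother = by_id.get(b.mother_id)
            if mother is None:
                raise CohortValidationError(
                    f"births row {i}: mother_id {b.mother_id!r} matches no "
                    f"female (orphan birth event)"
                )
            mother_age = age_at(mother, b.birth_date) if b.birth_date >= mother.birth_date else -1.0
            if mother_age < MIN_MATURATION_YEARS:
                raise CohortValidationError(
                    f"births row {i}: mother {b.mother_id!r} aged "
                    f"{mother_age:.2f} y at birth of {b.offspring_id!r}; "
                    f"minimum maturation age is {MIN_MATURATION_YEARS} y"
                )
            if b.birth_date > mother.exit_date:
                raise CohortValidationError(
                    f"births row {i}: birth of {b.offspring_id!r} after "
                    f"mother {b.mother_id!r} exit date {mother.exit_date}"
                )
            if b.offspring_exit_date is not None and b.offspring_exit_date < b.birth_date:
                raise CohortValidationError(
                    f"births row {i}: offspring_exit_date precedes birth_date"
                )
        return self


# ---------------------------------------------------------------------------
# CSV round trip


def _parse_date(token: str, *, where: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(token)
    except (TypeError, ValueError) as exc:
        raise CohortValidationError(f"{where}: unparseable date {token!r}") from exc


def _parse_enum(enum_cls, token: str, *, where: str):
    try:
        return enum_cls(token)
    except ValueError as exc:
        valid = ", ".join(e.value for e in enum_cls)
        raise CohortValidationError(
            f"{where}: unknown token {token!r} (expected one of: {valid})"
        ) from exc


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{path}: missing column(s) {missing}; expected {expected}"
        )


def read_cohort(
    females_path: Union[str, Path], births_path: Union[str, Path]
) -> Cohort:
    """Read and validate a cohort from the two-table CSV contract."""
    fdf = pd.read_csv(females_path, dtype=str, keep_default_na=False)
    bdf = pd.read_csv(births_path, dtype=str, keep_default_na=False)
    _check_columns(fdf, FEMALES_COLUMNS, females_path)
    _check_columns(bdf, BIRTHS_COLUMNS, births_path)

    females = []
    for i, row in fdf.iterrows():
        where = f"{females_path} row {i} (female_id={row['female_id']!r})"
        try:
            age_error = float(row["age_error_years"])
        except ValueError as exc:
            raise CohortValidationError(
                f"{where}: unparseable age_error_years {row['age_error_years']!r}"
            ) from exc
        females.append(
            FemaleRecord(
                female_id=row["female_id"],
                birth_date=_parse_date(row["birth_date"], where=where),
                age_error=age_error,
                entry_date=_parse_date(row["entry_date"], where=where),
                exit_date=_parse_date(row["exit_date"], where=where),
                exit_fate=_parse_enum(ExitFate, row["exit_fate"], where=where),
                entry_mode=_parse_enum(EntryMode, row["entry_mode"], where=where),
            )
        )

    births = []
    for i, row in bdf.iterrows():
        where = f"{births_path} row {i} (offspring_id={row['offspring_id']!r})"
        raw_exit = row["offspring_exit_date"]
        exit_date = None if raw_exit == "" else _parse_date(raw_exit, where=where)
        twin_token = row["is_twin_event"].strip().lower()
        if twin_token not in {"true", "false"}:
            raise CohortValidationError(
                f"{where}: is_twin_event must be 'true' or 'false', "
                f"got {row['is_twin_event']!r}"
            )
        births.append(
            BirthEvent(
                mother_id=row["mother_id"],
                offspring_id=row["offspring_id"],
                birth_date=_parse_date(row["birth_date"], where=where),
                offspring_exit_date=exit_date,
                offspring_exit_fate=_parse_enum(
                    ExitFate, row["offspring_exit_fate"], where=where
                ),
                is_twin_event=(twin_token == "true"),
            )
        )

    return Cohort(females=females, births=births).validate()


def write_cohort(
    cohort: Cohort,
    females_path: Union[str, Path],
    births_path: Union[str, Path],
) -> None:
    """Write a cohort to CSV so that ``read_cohort`` reproduces it exactly.

    Column order is fixed; rows keep the cohort's own ordering, so output is
    byte-stable for a given cohort.
    """
    cohort.validate()
    fdf = pd.DataFrame(
        [
            {
                "female_id": f.female_id,
                "birth_date": f.birth_date.isoformat(),
                "age_error_years": repr(f.age_error),
                "entry_date": f.entry_date.isoformat(),
                "exit_date": f.exit_date.isoformat(),
                "exit_fate": f.exit_fate.value,
                "entry_mode": f.entry_mode.value,
            }
            for f in cohort.females
        ],
        columns=FEMALES_COLUMNS,
    )
    bdf = pd.DataFrame(
        [
            {
                "mother_id": b.mother_id,
                "offspring_id": b.offspring_id,
                "birth_date": b.birth_date.isoformat(),
                "offspring_exit_date": (
                    "" if b.offspring_exit_date is None
                    else b.offspring_exit_date.isoformat()
                ),
                "offspring_exit_fate": b.offspring_exit_fate.value,
                "is_twin_event": "true" if b.is_twin_event else "false",
            }
            for b in cohort.births
        ],
        columns=BIRTHS_COLUMNS,
    )
    fdf.to_csv(females_path, index=False)
    bdf.to_csv(births_path, index=False)
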