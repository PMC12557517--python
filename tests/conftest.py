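import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from postrepro.data_io import (
    BirthEvent,
    Cohort,
    EntryMode,
    ExitFate,
    FemaleRecord,
)
from postrepro.demography import AgeObservations

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

BASE = dt.date(1980, 1, 1)


def days(years: float) -> dt.timedelta:
    return dt.timedelta(days=round(years * 365.25))


def female(
    fid: str,
    entry_age: float,
    exit_age: float,
    fate: ExitFate = ExitFate.DIED,
    birth: dt.date = BASE,
    age_error: float = 0.0,
    mode: EntryMode = EntryMode.HABITUATION,
) -> FemaleRecord:
    """Female built from ages relative to a fixed birth date (day-rounded)."""
    return FemaleRecord(
        female_id=fid,
        birth_date=birth,
        age_error=age_error,
        entry_date=birth + days(entry_age),
        exit_date=birth + days(exit_age),
        exit_fate=fate,
        entry_mode=mode,
    )


def birth(
    mother: FemaleRecord,
    mother_age: float,
    offspring_id: str,
    infant_death_age: float = None,
    twin: bool = False,
) -> BirthEvent:
    b = mother.birth_date + days(mother_age)
    if infant_death_age is None:
        exit_date, fate = None, ExitFate.ALIVE
    else:
        exit_date, fate = b + days(infant_death_age), ExitFate.DIED
    return BirthEvent(
        mother_id=mother.female_id,
        offspring_id=offspring_id,
        birth_date=b,
        offspring_exit_date=exit_date,
        offspring_exit_fate=fate,
        is_twin_event=twin,
    )


def obs(entry, exit_, died, birth_ages=(), mother_index=()) -> AgeObservations:
    """AgeObservations built directly from ages (bypasses calendar dates)."""
    return AgeObservations(
        entry=np.asarray(entry, dtype=float),
        exit=np.asarray(exit_, dtype=float),
        died=np.asarray(died, dtype=bool),
        birth_ages=np.asarray(birth_ages, dtype=float),
        mother_index=np.asarray(mother_index, dtype=int),
    )


@pytest.fixture
def toy_cohort() -> Cohort:
    """Three females, four births, one infant death."""
    a = female("A", 8.0, 30.0, ExitFate.DIED)
    b = female("B", 12.0, 40.0, ExitFate.ALIVE)
    c = female("C", 10.0, 24.0, ExitFate.EMIGRATED, age_error=2.0)
    births = [
        birth(a, 10.0, "A1"),
        birth(a, 15.0, "A2", infant_death_age=0.2),
        birth(b, 14.0, "B1"),
        birth(c, 12.0, "C1", twin=True),
    ]
    return Cohort(females=[a, b, c], births=births).validate()
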