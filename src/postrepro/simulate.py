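"""Individual-based life-history simulator for staggered-entry cohorts.

Generates cohorts with the structure the estimation pipeline assumes:
Gompertz (or piecewise-constant) mortality, a first birth around age ten,
interbirth intervals near five years with shorter returns after infant
deaths, optional reproductive cessation in the mid-thirties, and an
observation window that produces left truncation (habituation, immigration)
and right censoring (death, disappearance, emigration, study end), with
birth-date estimation errors for females not born in the study.

Default parameters are plausibility choices for wild mountain gorillas, not
estimates from any one population; see docs/methods.md.  All randomness
flows from a single seeded generator; the draw order (per female: lifespan,
cessation age, reproductive schedule, placement in calendar time, dispersal,
age error) is fixed, so a cohort is fully reproducible from its seed.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .data_io import (
    BirthEvent,
    Cohort,
    DAYS_PER_YEAR,
    EntryMode,
    ExitFate,
    FemaleRecord,
)
from .demography import exposure_schedule, fecundity_schedule, survivorship
from .prr import compute_prr

__all__ = ["SimConfig", "generate_cohort", "true_prr"]


def _years_to_days(y: float) -> _dt.timedelta:
    return _dt.timedelta(days=round(y * DAYS_PER_YEAR))


@dataclass
class MortalityConfig:
    """Female mortality.  ``gompertz``: hazard a·exp(b·age) — the standard
    model for mammalian actuarial senescence.  ``piecewise_constant``:
    constant hazard per interval, the analytically tractable alternative."""

    model: str = "gompertz"
    baseline_hazard: float = 0.015  # Gompertz a, deaths/year at age 0
    shape: float = 0.055  # Gompertz b, 1/years
    breakpoints: tuple = ()  # piecewise: interval upper bounds (years)
    rates: tuple = (0.03,)  # piecewise: hazard per interval

    def __post_init__(self):
        self.breakpoints = tuple(self.breakpoints)
        self.rates = tuple(self.rates)


@dataclass
class FirstBirthConfig:
    mean: float = 10.0
    sd: float = 1.5
    minimum: float = 8.0


@dataclass
class IBIConfig:
    """Successful interbirth intervals.  ``normal``: truncated normal draws.
    ``exponential``: memoryless waiting times with the same mean — a
    constant birth hazard across adult ages, used for null calibration."""

    mean: float = 5.1
    sd: float = 1.3
    minimum: float = 2.0
    model: str = "normal"


@dataclass
class InfantDeathConfig:
    """Infant loss and the shortened return to breeding that follows it."""

    probability: float = 0.25
    ibi_mean: float = 1.5
    ibi_sd: float = 0.75
    ibi_minimum: float = 0.5


@dataclass
class CessationConfig:
    """Reproductive cessation age (normal, clipped at the maturation
    minimum).  Disabled means reproduction continues until death."""

    enabled: bool = True
    mean: float = 35.0
    sd: float = 2.0


@dataclass
class ObservationConfig:
    """Study window and entry/exit processes.

    ``complete=True`` bypasses the observation model entirely: every female
    is followed from birth to death with no censoring, truncation or age
    error (used for ground-truth cohorts).
    """

    study_start: _dt.date = _dt.date(1993, 1, 1)
    study_end: _dt.date = _dt.date(2025, 1, 1)
    habituation_fraction: float = 0.5
    emigration_hazard: float = 0.02  # events per female-year after entry
    complete: bool = False


@dataclass
class AgeErrorConfig:
    max_years: float = 4.0  # uniform 0..max for habituated/immigrant females


@dataclass
class SimConfig:
    n_females: int = 25
    mortality: MortalityConfig = field(default_factory=MortalityConfig)
    age_first_birth: FirstBirthConfig = field(default_factory=FirstBirthConfig)
    ibi: IBIConfig = field(default_factory=IBIConfig)
    infant_death: InfantDeathConfig = field(default_factory=InfantDeathConfig)
    cessation: CessationConfig = field(default_factory=CessationConfig)
    max_age: float = 50.0
    observation: ObservationConfig = field(default_factory=ObservationConfig)
    age_error: AgeErrorConfig = field(default_factory=AgeErrorConfig)
    twin_probability: float = 0.01
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        for name, sd in (
            ("age_first_birth.sd", self.age_first_birth.sd),
            ("ibi.sd", self.ibi.sd),
            ("infant_death.ibi_sd", self.infant_death.ibi_sd),
            ("cessation.sd", self.cessation.sd),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0, got {sd}")
        if self.age_first_birth.minimum <= 0 or self.ibi.minimum <= 0:
            raise ValueError("minimum ages/intervals must be > 0")
        if self.age_first_birth.mean >= self.max_age:
            raise ValueError(
                "degenerate config: mean age at first birth >= max_age"
            )
        if not (0.0 <= self.observation.habituation_fraction <= 1.0):
            raise ValueError("habituation_fraction must lie in [0, 1]")
        if self.mortality.model not in ("gompertz", "piecewise_constant"):
            raise ValueError(f"unknown mortality model {self.mortality.model!r}")
        if self.ibi.model not in ("normal", "exponential"):
            raise ValueError(f"unknown ibi model {self.ibi.model!r}")
        if self.observation.study_end <= self.observation.study_start:
            raise ValueError("study_end must follow study_start")
        return self

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["observation"]["study_start"] = self.observation.study_start.isoformat()
        d["observation"]["study_end"] = self.observation.study_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = copy.deepcopy(d)
        obs = d.get("observation", {})
        for key in ("study_start", "study_end"):
            if key in obs and isinstance(obs[key], str):
                obs[key] = _dt.date.fromisoformat(obs[key])
        sub = {
            "mortality": MortalityConfig,
            "age_first_birth": FirstBirthConfig,
            "ibi": IBIConfig,
            "infant_death": InfantDeathConfig,
            "cessation": CessationConfig,
            "observation": ObservationConfig,
            "age_error": AgeErrorConfig,
        }
        kwargs = {}
        for key, value in d.items():
            if key in sub and isinstance(value, dict):
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# draws


def _draw_lifespan(cfg: MortalityConfig, max_age: float, rng) -> float:
    u = rng.random()
    if cfg.model == "gompertz":
        a, b = cfg.baseline_hazard, cfg.shape
        if b <= 0:
            t = -np.log(1 - u) / a  # reduces to exponential
        else:
            # invert S(t) = exp(-(a/b)(e^{bt} - 1))
            t = np.log(1.0 - (b / a) * np.log(1 - u)) / b
    else:
        edges = (0.0, *cfg.breakpoints, np.inf)
        target = -np.log(1 - u)
        cum = 0.0
        t = max_age
        for lo, hi, rate in zip(edges[:-1], edges[1:], cfg.rates):
            width = hi - lo
            if rate <= 0:
                if not np.isfinite(width):
                    break
                continue
            seg = rate * width
            if cum + seg >= target:
                t = lo + (target - cum) / rate
                break
            cum += seg
    return float(min(t, max_age))


def _truncated_normal(mean, sd, minimum, rng, max_tries=1000) -> float:
    if sd == 0:
        return max(mean, minimum)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x >= minimum:
            return float(x)
    raise ValueError(
        f"could not draw normal({mean}, {sd}) above {minimum}: "
        f"degenerate configuration"
    )


def _reproductive_schedule(config: SimConfig, lifespan: float,
                           cessation_age: float, rng):
    """Ages at parity events plus, per event, (infant_died, infant death age
    offset or None, is_twin)."""
    fb, ibi, inf = config.age_first_birth, config.ibi, config.infant_death
    if config.ibi.model == "exponential":
        # memoryless from maturation: constant birth hazard across adult ages
        age = fb.minimum + rng.exponential(ibi.mean)
    else:
        age = _truncated_normal(fb.mean, fb.sd, fb.minimum, rng)
    events = []
    while age < min(lifespan, cessation_age):
        died = rng.random() < inf.probability
        twin = rng.random() < config.twin_probability
        if died:
            death_offset = rng.uniform(0.05, 0.5)
            gap = max(
                _truncated_normal(inf.ibi_mean, inf.ibi_sd, inf.ibi_minimum, rng),
                death_offset + 0.1,
            )
        else:
            death_offset = None
            if ibi.model == "exponential":
                gap = rng.exponential(ibi.mean)
            else:
                gap = _truncated_normal(ibi.mean, ibi.sd, ibi.minimum, rng)
        events.append((age, died, death_offset, twin))
        age += gap
    return events


def generate_cohort(config: SimConfig, seed=None) -> Cohort:
    """Simulate a cohort of observed female life histories.

    Females whose lives never intersect the study window, or who would be
    observed for under a month, are redrawn — observational records only
    ever contain observed individuals;
    parity events are recorded only when they fall inside the mother's
    observation window, unless ``observation.complete`` is set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    obs = config.observation
    start, end = obs.study_start, obs.study_end
    window_years = (end - start).days / DAYS_PER_YEAR

    females: list[FemaleRecord] = []
    births: list[BirthEvent] = []

    for i in range(config.n_females):
        fid = f"F{i:03d}"
        placed = False
        for _ in range(200):  # redraw lives that can never be observed
            lifespan = _draw_lifespan(config.mortality, config.max_age, rng)
            if config.cessation.enabled:
                cessation_age = _truncated_normal(
                    config.cessation.mean, config.cessation.sd,
                    config.age_first_birth.minimum, rng,
                )
            else:
                cessation_age = np.inf
            events = _reproductive_schedule(config, lifespan, cessation_age, rng)
            if obs.complete or lifespan * DAYS_PER_YEAR >= 30:
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not draw an observable life history; "
                "degenerate mortality configuration"
            )

        if obs.complete:
            birth_cal = start
            entry_cal = birth_cal
            death_cal = birth_cal + _years_to_days(lifespan)
            exit_cal, fate = death_cal, ExitFate.DIED
            mode, age_error = EntryMode.BORN_IN_STUDY, 0.0
            observed = events
        else:
            # place the life in calendar time; condition on being observed
            for _ in range(1000):
                birth_offset = rng.uniform(-0.8 * config.max_age, window_years - 2.0)
                birth_cal = start + _years_to_days(birth_offset)
                death_cal = birth_cal + _years_to_days(lifespan)
                if birth_cal >= start:
                    mode = EntryMode.BORN_IN_STUDY
                    entry_cal = birth_cal
                elif death_cal <= start:
                    continue  # died before the study began
                elif rng.random() < obs.habituation_fraction:
                    mode = EntryMode.HABITUATION
                    entry_cal = start
                else:
                    mode = EntryMode.IMMIGRATION
                    horizon = min(death_cal, end)
                    span_days = (horizon - start).days
                    if span_days < 30:
                        continue
                    entry_cal = start + _dt.timedelta(
                        days=int(rng.uniform(0, span_days))
                    )
                if obs.emigration_hazard > 0:
                    emig_cal = entry_cal + _years_to_days(
                        rng.exponential(1.0 / obs.emigration_hazard)
                    )
                else:
                    emig_cal = None
                exit_cal = min(
                    c for c in (death_cal, emig_cal, end) if c is not None
                )
                if (exit_cal - entry_cal).days < 30:
                    continue  # effectively unobserved
                if exit_cal == death_cal:
                    fate = ExitFate.DIED
                elif emig_cal is not None and exit_cal == emig_cal:
                    fate = (
                        ExitFate.EMIGRATED
                        if rng.random() < 0.5
                        else ExitFate.DISAPPEARED
                    )
                else:
                    fate = ExitFate.ALIVE
                break
            else:
                raise ValueError(
                    "could not place a female inside the study window; "
                    "degenerate observation configuration"
                )
            age_error = (
                0.0
                if mode is EntryMode.BORN_IN_STUDY
                else float(rng.uniform(0.0, config.age_error.max_years))
            )
            entry_age = (entry_cal - birth_cal).days / DAYS_PER_YEAR
            observed = []
            for ev in events:
                ev_cal = birth_cal + _years_to_days(ev[0])
                if entry_cal <= ev_cal <= exit_cal:
                    observed.append(ev)
                elif ev_cal < entry_cal and not ev[1] and entry_age - ev[0] < 8.0:
                    # pre-entry birth back-identified from the surviving
                    # offspring still accompanying the mother as a juvenile
                    observed.append(ev)

        females.append(
            FemaleRecord(
                female_id=fid,
                birth_date=birth_cal,
                age_error=age_error,
                entry_date=entry_cal,
                exit_date=exit_cal,
                exit_fate=fate,
                entry_mode=mode,
            )
        )
        for j, (age, inf_died, death_offset, twin) in enumerate(observed):
            off_birth = birth_cal + _years_to_days(age)
            if inf_died:
                off_exit = off_birth + _years_to_days(death_offset)
                off_fate = ExitFate.DIED
            else:
                off_exit, off_fate = None, ExitFate.ALIVE
            births.append(
                BirthEvent(
                    mother_id=fid,
                    offspring_id=f"{fid}-O{j}",
                    birth_date=off_birth,
                    offspring_exit_date=off_exit,
                    offspring_exit_fate=off_fate,
                    is_twin_event=twin,
                )
            )

    return Cohort(females=females, births=births).validate()


def true_prr(
    config: SimConfig,
    n_cohort: int = 20_000,
    seed=None,
    weighting: str = "l_times_m",
    denominator: str = "females_observed",
) -> float:
    """Ground-truth PrR of the generating process.

    Computed on a very large cohort of *complete* life histories — no
    truncation, no censoring, no age error — so it is the recovery target
    for the estimation pipeline run on observational data from the same
    configuration.
    """
    cfg = copy.deepcopy(config)
    cfg.n_females = n_cohort
    cfg.observation = ObservationConfig(
        study_start=config.observation.study_start,
        study_end=config.observation.study_end,
        complete=True,
    )
    cohort = generate_cohort(cfg, seed=cfg.seed if seed is None else seed)
    schedule = fecundity_schedule(exposure_schedule(cohort), denominator)
    curve = survivorship(cohort, method="product_limit")
    return compute_prr(curve, schedule, weighting).prr
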