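"""Synthetic tagged cohorts with the statistical structure the estimators assume.

Animals enter the study at a release age (months), face a piecewise-constant
daily mortality hazard within each age-year (``DMR = 1 - s**(1/365.25)`` for
that year's annual survival ``s``), and are censored at the study horizon.
Deaths are predation with an age-class-specific probability; each implanted
tag independently fails to uplink with a fixed probability, and an event is
detected when at least one tag reports.  Detected events carry a synthetic
temperature profile in one of two archetypes: a precipitous drop with
immediate extrusion (predation) or gradual Newtonian cooling with delayed
extrusion (non-traumatic death).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CoolingParams, MortalityEvent
from .survival import DAYS_PER_MONTH, DAYS_PER_YEAR


@dataclass(frozen=True)
class CohortSpec:
    """Design of one simulated deployment cohort."""

    n_animals: int
    annual_survival_by_ageclass: dict[int, float]  # age-year -> annual survival
    pp_by_ageclass: dict[int, float] = field(default_factory=dict)  # age-year -> P(predation | death)
    sex_ratio_male: float = 28.0 / 36.0
    release_age_months: int = 13
    horizon_months: int = 60
    p_fail_true: float = 0.1
    tags_per_animal: int = 2
    ambient_c: float = 8.0
    mass_kg: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for name, val in [("sex_ratio_male", self.sex_ratio_male), ("p_fail_true", self.p_fail_true)]:
            if not 0.0 <= val <= 1.0 or (name == "p_fail_true" and val >= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1)")
        if self.horizon_months < self.release_age_months:
            raise ValueError("horizon must not precede release age")
        if self.tags_per_animal not in (1, 2):
            raise ValueError("tags_per_animal must be 1 or 2")
        for year, s in self.annual_survival_by_ageclass.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"annual survival for age-year {year} outside (0, 1]")
        for year, pp in self.pp_by_ageclass.items():
            if not 0.0 <= pp <= 1.0:
                raise ValueError(f"pp for age-year {year} outside [0, 1]")


@dataclass
class SimulatedAnimal:
    animal_id: str
    sex: str
    entry_age_months: float
    exit_age_months: float
    fate: str  # died | censored
    cause_true: str  # predation | non_traumatic | none
    tag_outcomes: tuple[bool, ...]  # per-tag uplink success
    detected: bool

    def __post_init__(self) -> None:
        if self.exit_age_months < self.entry_age_months:
            raise ValueError("exit before entry")
        if (self.cause_true == "none") != (self.fate == "censored"):
            raise ValueError("cause_true must be 'none' exactly for censored animals")


def daily_mortality_rate(annual_survival: float) -> float:
    """Constant within-year daily hazard implied by an annual survival."""
    return 1.0 - annual_survival ** (1.0 / DAYS_PER_YEAR)


def generate_temperature_profile(
    cause: str,
    mass_kg: float,
    ambient_c: float,
    params: CoolingParams = CoolingParams(),
    rng_seed: int | np.random.Generator = 0,
    duration_h: float = 48.0,
    step_h: float = 0.25,
    mass_fraction: float = 1.0,
    delay_mean_h: float = 24.0,
) -> tuple[np.ndarray, float, list[tuple[float, str]]]:
    """Synthesise a post-mortem temperature series for one archetype.

    Predation: a step-like drop reaching ambient within minutes, zero
    extrusion delay, tag immediately in saltwater.  Non-traumatic: Newtonian
    decay with rate set by the effective cooling mass (``mass_kg *
    mass_fraction``), extrusion delay drawn from a positive lognormal with
    the given mean.  Gaussian sensor noise with ``params.noise_sd`` is added
    throughout.  Returns ``(series (n, 2), extrusion delay h, medium
    sequence)``.
    """
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    if ambient_c >= params.body_temp_c:
        raise ValueError("ambient must be below body temperature")
    if cause not in ("predation", "non_traumatic"):
        raise ValueError(f"unknown cause {cause!r}")
    rng = np.random.default_rng(rng_seed)
    t = np.arange(0.0, duration_h + step_h / 2, step_h)
    amp = params.body_temp_c - ambient_c
    if cause == "predation":
        k = 60.0  # 1/h: equilibrated within a few minutes
        delay = 0.0
        media = [(0.0, "tissue"), (0.0, "saltwater")]
    else:
        k = params.rate_for_mass(mass_kg * mass_fraction)
        delay = float(rng.lognormal(mean=math.log(delay_mean_h), sigma=0.4))
        media = [(0.0, "tissue"), (delay, "saltwater")]
    temp = ambient_c + amp * np.exp(-k * t)
    temp = temp + rng.normal(0.0, params.noise_sd, size=t.shape)
    return np.column_stack([t, temp]), delay, media


def _ageclass_lookup(mapping: dict[int, float], default: float) -> dict[int, float]:
    return {int(k): float(v) for k, v in mapping.items()} if mapping else {1: default}


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[SimulatedAnimal], pd.DataFrame, list[MortalityEvent]]:
    """Simulate one cohort; deterministic for a fixed ``rng_seed``.

    Returns the animals, an exposure ledger (one row per animal, months of
    age at entry/exit, fate), and the mortality events for the deaths —
    events are generated for every death and flagged ``detected`` according
    to the per-tag uplink outcome.
    """
    rng = np.random.default_rng(spec.rng_seed)
    animals: list[SimulatedAnimal] = []
    events: list[MortalityEvent] = []
    surv = spec.annual_survival_by_ageclass
    for idx in range(spec.n_animals):
        sex = "male" if rng.random() < spec.sex_ratio_male else "female"
        entry_m = float(spec.release_age_months)
        # continuous age in month labels: month label m spans [m, m + 1)
        horizon_end = float(spec.horizon_months) + 1.0
        age_m = entry_m
        death_age_m: float | None = None
        while age_m < horizon_end:
            year = int((age_m - 1.0) // 12.0) + 1  # months 13..24 -> year 2
            seg_end = min(horizon_end, 12.0 * year + 1.0)
            s_year = surv.get(year, 1.0)
            if s_year < 1.0:
                dmr = daily_mortality_rate(s_year)
                seg_days = (seg_end - age_m) * DAYS_PER_MONTH
                u = rng.random()
                if u < 1.0 - (1.0 - dmr) ** seg_days:
                    day = math.log(1.0 - u) / math.log(1.0 - dmr)
                    death_age_m = age_m + day / DAYS_PER_MONTH
                    break
            age_m = seg_end
        if death_age_m is None:
            animals.append(
                SimulatedAnimal(
                    animal_id=f"A{idx:05d}",
                    sex=sex,
                    entry_age_months=entry_m,
                    exit_age_months=float(spec.horizon_months),
                    fate="censored",
                    cause_true="none",
                    tag_outcomes=(),
                    detected=False,
                )
            )
            continue
        year = int((death_age_m - 1) // 12) + 1
        pp = spec.pp_by_ageclass.get(year, 0.0)
        cause = "predation" if rng.random() < pp else "non_traumatic"
        uplinks = tuple(bool(rng.random() >= spec.p_fail_true) for _ in range(spec.tags_per_animal))
        detected = any(uplinks)
        animal = SimulatedAnimal(
            animal_id=f"A{idx:05d}",
            sex=sex,
            entry_age_months=entry_m,
            exit_age_months=death_age_m,
            fate="died",
            cause_true=cause,
            tag_outcomes=uplinks,
            detected=detected,
        )
        animals.append(animal)
        series, delay, media = generate_temperature_profile(
            cause,
            spec.mass_kg,
            spec.ambient_c,
            rng_seed=rng,
        )
        events.append(
            MortalityEvent(
                event_id=f"E{idx:05d}",
                age_at_death_months=death_age_m,
                temp_series=series,
                medium_series=media,
                transmission_delay_h=delay,
                ambient_c=spec.ambient_c,
                expected_mass_kg=spec.mass_kg,
                detected=detected,
            )
        )
    ledger = pd.DataFrame(
        {
            "animal_id": [a.animal_id for a in animals],
            "sex": [a.sex for a in animals],
            "entry_age_months": [a.entry_age_months for a in animals],
            "exit_age_months": [a.exit_age_months for a in animals],
            "fate": [a.fate for a in animals],
            "event_id": [
                f"E{idx:05d}" if a.fate == "died" else None for idx, a in enumerate(animals)
            ],
        }
    )
    return animals, ledger, events
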