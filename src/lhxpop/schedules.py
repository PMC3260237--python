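"""Vital-rate schedules and birth-pulse population vectors.

A schedule lists, per sex and age-year ``i = 1..31``, the fraction ``s_i``
of animals entering year ``i`` that survive it, the proportion ``pp_i`` of
that year's mortality attributed to predation, and the implied mortality
partitions ``m_p,i = (1 - s_i) pp_i`` (consumed by predators) and
``m_np,i = (1 - s_i)(1 - pp_i)`` (all other causes), so that
``s_i + m_p,i + m_np,i = 1`` for every year.

Population vectors follow a post-breeding birth-pulse census: a pup seed
(both sexes, 1:1 at birth) enters year 1 and each cohort is thinned by the
survival schedule; the terminal year 31 is closed (its survivors are
treated as deaths for conservation accounting, partitioned like the rest of
that year's mortality).  *Minimum natality* — the birth rate that exactly
balances the schedule — is the seed divided by the number of females in the
reproductive ages 5-21 inclusive, i.e. ``2 / sum_{i=5..21} l_i`` with
``l_i`` the survivorship to the start of year ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

N_AGES = 31
REPRO_AGES = (5, 21)  # inclusive, in completed years of age
# a female aged 5-21 completed years is in year-class 6-22
REPRO_CLASSES = (REPRO_AGES[0] + 1, REPRO_AGES[1] + 1)
PARTITION_TOL = 1e-9


@dataclass
class VitalSchedule:
    """Per-sex survival / predation-share schedule over age-years 1..31."""

    sex: str
    s: np.ndarray  # annual survival, length 31
    pp: np.ndarray  # proportion of (1 - s) attributed to predation

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.pp = np.asarray(self.pp, dtype=float)
        if self.s.shape != (N_AGES,) or self.pp.shape != (N_AGES,):
            raise ValueError(f"schedules must cover {N_AGES} age-years")
        if np.any((self.s <= 0) & (np.arange(N_AGES) < N_AGES - 1)) or np.any(self.s > 1):
            raise ValueError("survival values must lie in (0, 1]")
        if np.any(self.pp < 0) or np.any(self.pp > 1):
            raise ValueError("pp values must lie in [0, 1]")

    @property
    def m_p(self) -> np.ndarray:
        return (1.0 - self.s) * self.pp

    @property
    def m_np(self) -> np.ndarray:
        return (1.0 - self.s) * (1.0 - self.pp)

    @property
    def survivorship(self) -> np.ndarray:
        """l_i: fraction of the birth cohort alive at the start of year i."""
        return np.concatenate([[1.0], np.cumprod(self.s)[:-1]])

    def effective_s(self) -> np.ndarray:
        """Survival with the terminal year closed (s_31 -> 0)."""
        s = self.s.copy()
        s[-1] = 0.0
        return s

    def effective_m_np(self) -> np.ndarray:
        s = self.effective_s()
        return (1.0 - s) * (1.0 - self.pp)

    def effective_m_p(self) -> np.ndarray:
        s = self.effective_s()
        return (1.0 - s) * self.pp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": self.sex,
                "age_year": np.arange(1, N_AGES + 1),
                "s": self.s,
                "pp": self.pp,
                "m_p": self.m_p,
                "m_np": self.m_np,
            }
        )


@dataclass
class PopulationVectors:
    """Absolute counts per sex and age-year from a birth-pulse seed."""

    seed: float
    n: dict[str, np.ndarray]  # alive entering year i
    p: dict[str, np.ndarray]  # consumed by predators during year i
    d: dict[str, np.ndarray]  # died of other causes during year i

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.n.values()))

    def total_by_sex(self, sex: str) -> float:
        return float(self.n[sex].sum())


@dataclass
class MinimumNatality:
    value: float
    repro_ages: tuple[int, int] = REPRO_AGES


def write_schedules(schedules: list[VitalSchedule], path) -> None:
    pd.concat([s.to_frame() for s in schedules]).to_csv(path, index=False)


def load_schedule(path_or_buf, sex: str | None = None) -> VitalSchedule:
    """Read one schedule from CSV (columns sex, age_year, s, pp, m_p, m_np).

    The mortality-partition identity ``s + m_p + m_np = 1`` is enforced per
    row to 1e-9; a violation raises with the offending sex and age-year.
    """
    df = pd.read_csv(path_or_buf)
    if sex is not None:
        df = df[df.sex == sex]
    sexes = df.sex.unique()
    if len(sexes) != 1:
        raise ValueError(f"expected a single sex in schedule file, found {list(sexes)}")
    df = df.sort_values("age_year")
    if list(df.age_year) != list(range(1, N_AGES + 1)):
        raise ValueError("schedule must list age-years 1..31 exactly once each")
    bad = np.abs(df.s + df.m_p + df.m_np - 1.0) > PARTITION_TOL
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"partition identity s + m_p + m_np = 1 violated at sex={row.sex} "
            f"age_year={int(row.age_year)}"
        )
    mort = 1.0 - df.s.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pp = np.where(mort > 0, df.m_p.to_numpy() / np.where(mort > 0, mort, 1.0), df.pp.to_numpy())
    return VitalSchedule(sex=str(sexes[0]), s=df.s.to_numpy(), pp=pp)


def set_pp_schedule(schedule: VitalSchedule, pp_juvenile: float) -> VitalSchedule:
    """Attach the age-structured predation-share schedule.

    Young-of-the-year carry 30% of the juvenile PP; juveniles (years 2-5)
    carry it fully; above year 5 the share halves each year, reflecting
    reduced vulnerability with age, size and experience.
    """
    if not 0.0 <= pp_juvenile <= 1.0:
        raise ValueError("pp_juvenile must lie in [0, 1]")
    ages = np.arange(1, N_AGES + 1)
    pp = np.where(
        ages == 1,
        0.3 * pp_juvenile,
        np.where(ages <= 5, pp_juvenile, pp_juvenile * 0.5 ** (ages - 5)),
    )
    return replace(schedule, pp=pp)


def build_lhx_egoa(
    base: VitalSchedule,
    lhx_annual: dict[int, float],
    pup_rate_year1: float,
    adult_scale: float = 1.13,
    published_scale: float = 1.07,
    pp_juvenile: float | None = None,
) -> VitalSchedule:
    """Replace the youngest five years of a base schedule and rescale adults.

    Years 2-5 take the telemetry-based annual survivals, year 1 the supplied
    young-of-the-year rate.  Adult survivals (years >= 6) are multiplied by
    ``adult_scale / published_scale`` — the base schedule already embodies
    the published adult scaling — and capped at 1.
    """
    if not 0.0 < pup_rate_year1 <= 1.0:
        raise ValueError("pup_rate_year1 must lie in (0, 1]")
    if sorted(lhx_annual) != [2, 3, 4, 5]:
        raise ValueError("lhx_annual must supply years 2-5")
    if adult_scale <= 0:
        raise ValueError("adult_scale must be positive")
    s = base.s.copy()
    s[0] = pup_rate_year1
    for year, rate in lhx_annual.items():
        if not 0.0 < rate <= 1.0:
            raise ValueError(f"annual survival for year {year} outside (0, 1]")
        s[year - 1] = rate
    scaled = s[5:] * (adult_scale / published_scale)
    if np.any(scaled > 1.0):
        import warnings

        warnings.warn("scaled adult survival exceeded 1 and was capped", stacklevel=2)
    s[5:] = np.minimum(scaled, 1.0)
    out = replace(base, s=s)
    if pp_juvenile is not None:
        out = set_pp_schedule(out, pp_juvenile)
    return out


def derive_male_schedule(female: VitalSchedule, decay: float) -> VitalSchedule:
    """Male schedule as a progressively decreasing proportion of female rates.

    Years 1-5 are shared; above year 5 the male survival is the female value
    times ``(1 - decay) ** (i - 5)`` — geometric, one parameter, decreasing
    in age.  ``decay = 0`` reproduces the female schedule.
    """
    if not 0.0 <= decay < 1.0:
        raise ValueError("decay must lie in [0, 1)")
    ages = np.arange(1, N_AGES + 1)
    g = np.where(ages <= 5, 1.0, (1.0 - decay) ** (ages - 5))
    s = np.clip(female.s * g, 1e-12, 1.0)
    return VitalSchedule(sex="male", s=s, pp=female.pp.copy())


def percentile_age(schedule: VitalSchedule, q: float = 0.95) -> float:
    """Continuous age (years) below which a fraction q of the stationary
    population lies, by linear interpolation over whole-year counts."""
    l = schedule.survivorship
    cum = np.cumsum(l) / l.sum()
    j = int(np.searchsorted(cum, q))
    prev = cum[j - 1] if j > 0 else 0.0
    frac = (q - prev) / (cum[j] - prev)
    return float(j + frac)


def calibrate_male_decay(
    female: VitalSchedule, target_p95: float = 14.0, tol: float = 1e-10
) -> float:
    """Bisection for the geometric decay putting 95% of males within the
    target age.  Raises with the achieved percentile range if unattainable."""
    from scipy.optimize import brentq

    def f(decay: float) -> float:
        return percentile_age(derive_male_schedule(female, decay)) - target_p95

    lo, hi = 0.0, 0.6
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"male-decay calibration infeasible: p95 range [{fhi + target_p95:.2f}, "
            f"{flo + target_p95:.2f}] does not bracket {target_p95}"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def population_vectors(
    female: VitalSchedule, male: VitalSchedule, seed: float
) -> PopulationVectors:
    """Deterministic birth-pulse vectors (1:1 sex ratio at birth).

    Conservation is exact: per sex, predation deaths + other deaths sum to
    the half-seed, because the terminal year is closed.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    n, p, d = {}, {}, {}
    for sched in (female, male):
        s_eff = sched.effective_s()
        l = np.concatenate([[1.0], np.cumprod(s_eff)[:-1]])
        ni = seed / 2.0 * l
        deaths = ni * (1.0 - s_eff)
        n[sched.sex] = ni
        p[sched.sex] = deaths * sched.pp
        d[sched.sex] = deaths * (1.0 - sched.pp)
    return PopulationVectors(seed=seed, n=n, p=p, d=d)


def minimum_natality(female: VitalSchedule) -> MinimumNatality:
    """Pups per reproductive female per year balancing the schedule.

    Equals ``2 / sum l_i`` over the reproductive year-classes (both-sex seed
    over females aged 5-21 completed years, i.e. year-classes 6-22),
    independent of seed scale and of the male schedule.
    """
    lo, hi = REPRO_CLASSES
    denom = float(female.survivorship[lo - 1 : hi].sum())
    if denom <= 0:
        raise ValueError("no females reach reproductive age under this schedule")
    return MinimumNatality(value=2.0 / denom)


def calibrate_seed(female: VitalSchedule, male: VitalSchedule, target_total: float) -> float:
    """Seed whose both-sex vector total equals the target (linear, exact)."""
    if target_total < 0:
        raise ValueError("target_total must be >= 0")
    unit = population_vectors(female, male, 1.0).total
    return target_total / unit
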