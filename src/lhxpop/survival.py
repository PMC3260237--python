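"""Mayfield-style survival estimation from exposure days.

The daily mortality rate within an age class is the corrected event count
divided by cumulative exposure days, ``DMR = E_corr / d_exp``; the daily
survival rate is ``DSR = 1 - DMR`` and survival over longer periods is
``DSR`` raised to the period length in days (annual rates use 365.25 by
default).  Variances follow Johnson's estimator
``var(DSR) = e (d - e) / d**3`` with a delta-method transfer to the period
scale.  A tag-failure-adjusted lower confidence limit recomputes the
Johnson lower bound with the corrected event count set to its upper
confidence limit (and exposure reduced by half a period per added event,
the usual midpoint convention for undated deaths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DAYS_PER_MONTH = 365.25 / 12.0
DAYS_PER_YEAR = 365.25

LEDGER_COLUMNS = ["animal_id", "sex", "entry_age_months", "exit_age_months", "fate", "event_id"]


@dataclass
class AgeClassExposure:
    """Exposure and event tallies for one age class (months, inclusive)."""

    age_class: tuple[int, int]
    d_exp: float
    n_events_detected: int
    n_animals: int
    n_events_corrected: float | None = None


@dataclass
class SurvivalEstimate:
    age_class: tuple[int, int] | None
    dmr: float
    dsr: float
    period_days: float
    period_survival: float
    ci95: tuple[float, float] | None = None
    ci_method: str = "johnson"


def validate_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    """Check the per-animal exposure ledger; returns it unchanged."""
    missing = [c for c in LEDGER_COLUMNS[:5] if c not in ledger.columns]
    if missing:
        raise ValueError(f"ledger missing columns: {missing}")
    if (ledger.exit_age_months < ledger.entry_age_months).any():
        bad = ledger.loc[ledger.exit_age_months < ledger.entry_age_months, "animal_id"].tolist()
        raise ValueError(f"exit before entry for animals {bad}")
    if not ledger.fate.isin(["died", "censored"]).all():
        raise ValueError("fate must be 'died' or 'censored'")
    return ledger


def load_ledger(path) -> pd.DataFrame:
    return validate_ledger(pd.read_csv(path))


def bin_exposure(ledger: pd.DataFrame, bounds: list[int] | None = None) -> list[AgeClassExposure]:
    """Bin animal-months at risk into age classes and tally events.

    ``bounds`` are month cut-points, default ``[13, 25, 37, 49, 61]`` giving
    the classes 13-24, 25-36, 37-48 and 49-60 months.  Ages are 1-based
    month labels: an animal at risk from month 13 through month 24 inclusive
    contributes twelve months (365.25 days) to the first class.  Fractional
    exit ages are supported; deaths are assigned to the class containing the
    month of death.
    """
    validate_ledger(ledger)
    if bounds is None:
        bounds = [13, 25, 37, 49, 61]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("age-class bounds must be strictly increasing")
    classes = [(lo, hi - 1) for lo, hi in zip(bounds, bounds[1:])]
    # at-risk span in month-label space: [entry, exit + 1) for censored
    # animals (month `exit` completed); deaths end at the exact exit age.
    end = ledger.exit_age_months.to_numpy(float) + np.where(
        ledger.fate.to_numpy() == "censored", 1.0, 0.0
    )
    out = []
    for lo, hi in classes:
        a = np.maximum(ledger.entry_age_months.to_numpy(float), lo)
        b = np.minimum(end, hi + 1.0)
        months = np.clip(b - a, 0.0, None)
        died_here = (
            (ledger.fate == "died")
            & (np.floor(ledger.exit_age_months) >= lo)
            & (np.floor(ledger.exit_age_months) <= hi)
        )
        out.append(
            AgeClassExposure(
                age_class=(lo, hi),
                d_exp=float(months.sum() * DAYS_PER_MONTH),
                n_events_detected=int(died_here.sum()),
                n_animals=int((months > 0).sum()),
            )
        )
    return out


def annual_survival(e_count: float, d_exp: float, period_days: float = DAYS_PER_YEAR) -> SurvivalEstimate:
    """Point Mayfield estimate of survival over ``period_days``."""
    if d_exp <= 0:
        raise ValueError("d_exp must be positive")
    if e_count > d_exp:
        raise ValueError("more events than exposure days")
    dmr = e_count / d_exp
    dsr = 1.0 - dmr
    return SurvivalEstimate(
        age_class=None, dmr=dmr, dsr=dsr, period_days=period_days, period_survival=dsr**period_days
    )


def johnson_ci(
    e_count: float, d_exp: float, period_days: float = DAYS_PER_YEAR, alpha: float = 0.05
) -> tuple[float, float]:
    """Johnson-variance normal-quantile CI on the period-survival scale.

    ``var(DSR) = e (d - e) / d**3``; the delta method carries the standard
    error to the period scale through ``period * DSR**(period - 1)``.  With
    zero events the upper limit is 1 and the lower limit comes from the
    one-sided rule-of-three bound (3 pseudo-events at the same exposure).
    """
    est = annual_survival(e_count, d_exp, period_days)
    if e_count == 0:
        lo = (1.0 - 3.0 / d_exp) ** period_days
        return (max(0.0, lo), 1.0)
    var_dsr = e_count * (d_exp - e_count) / d_exp**3
    se_period = period_days * est.dsr ** (period_days - 1.0) * math.sqrt(var_dsr)
    z = norm.ppf(1.0 - alpha / 2.0)
    return (
        max(0.0, est.period_survival - z * se_period),
        min(1.0, est.period_survival + z * se_period),
    )


def pfail_adjusted_lower_cl(
    e_upper: float,
    detected: float,
    d_exp: float,
    period_days: float = DAYS_PER_YEAR,
    alpha: float = 0.05,
) -> float:
    """Lower survival limit re-computed at the upper corrected event count.

    Each event added beyond the detected count removes half a period of
    exposure (death at the interval midpoint).  The upper survival limit is
    unchanged by construction and not returned here.
    """
    if e_upper < detected:
        raise ValueError("e_upper must be >= detected count")
    d_adj = d_exp - (e_upper - detected) * period_days / 2.0
    if d_adj <= 0:
        raise ValueError("exposure reduction exceeds available exposure")
    return johnson_ci(e_upper, d_adj, period_days, alpha)[0]


def estimate_age_class(
    exp: AgeClassExposure,
    e_corr_upper: float | None = None,
    period_days: float = DAYS_PER_YEAR,
    alpha: float = 0.05,
) -> SurvivalEstimate:
    """Full per-class estimate: point, Johnson CI, optional P_fail-adjusted lower."""
    e = exp.n_events_corrected if exp.n_events_corrected is not None else exp.n_events_detected
    est = annual_survival(e, exp.d_exp, period_days)
    est.age_class = exp.age_class
    lo, hi = johnson_ci(e, exp.d_exp, period_days, alpha)
    method = "johnson"
    if e_corr_upper is not None and e_corr_upper > exp.n_events_detected:
        lo = min(lo, pfail_adjusted_lower_cl(e_corr_upper, e, exp.d_exp, period_days, alpha))
        method = "johnson_pfail_adjusted"
    est.ci95 = (lo, hi)
    est.ci_method = method
    return est


def cumulative_survival(estimates: list[SurvivalEstimate]) -> SurvivalEstimate:
    """Product of contiguous per-class survivals, CIs multiplied classwise."""
    if not estimates:
        raise ValueError("no estimates to combine")
    for a, b in zip(estimates, estimates[1:]):
        if a.age_class and b.age_class and a.age_class[1] + 1 != b.age_class[0]:
            raise ValueError(f"age classes not contiguous at {a.age_class} -> {b.age_class}")
    point = float(np.prod([e.period_survival for e in estimates]))
    if all(e.ci95 is not None for e in estimates):
        ci = (
            float(np.prod([e.ci95[0] for e in estimates])),
            float(np.prod([e.ci95[1] for e in estimates])),
        )
    else:
        ci = None
    lo = estimates[0].age_class[0] if estimates[0].age_class else 0
    hi = estimates[-1].age_class[1] if estimates[-1].age_class else 0
    total_days = float(sum(e.period_days for e in estimates))
    dsr = point ** (1.0 / total_days)
    return SurvivalEstimate(
        age_class=(lo, hi),
        dmr=1.0 - dsr,
        dsr=dsr,
        period_days=total_days,
        period_survival=point,
        ci95=ci,
        ci_method=estimates[0].ci_method,
    )
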