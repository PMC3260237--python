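"""Mayfield exposure-day survival estimation."""

import numpy as np
import pandas as pd
import pytest

from lhxpop import reference as ref
from lhxpop.survival import (
    annual_survival,
    bin_exposure,
    cumulative_survival,
    estimate_age_class,
    johnson_ci,
    pfail_adjusted_lower_cl,
)
from lhxpop.synthcohort import CohortSpec, simulate_cohort


def _ledger(rows):
    return pd.DataFrame(
        rows, columns=["animal_id", "sex", "entry_age_months", "exit_age_months", "fate", "event_id"]
    )


def test_bin_exposure_full_year_span():
    led = _ledger([("a", "m", 13, 24, "censored", None)])
    classes = bin_exposure(led)
    assert classes[0].d_exp == pytest.approx(365.25, abs=1e-9)
    assert all(c.d_exp == 0 for c in classes[1:])
    assert classes[0].n_animals == 1


def test_bin_exposure_reproduces_study_table(study_ledger):
    """The reconstructed per-animal ledger bins to the published exposure
    table: 35/25/18/15 animals, 5757/7763/5979/4573 days, 7/4/0/1 events."""
    classes = bin_exposure(study_ledger)
    for got, (cls, n, d_exp, events) in zip(classes, ref.EXPOSURE_TABLE):
        assert got.age_class == cls
        assert got.n_animals == n
        assert got.d_exp == pytest.approx(d_exp, abs=1e-6)
        assert got.n_events_detected == events


def test_bin_exposure_empty_ledger_and_bad_bounds():
    empty = _ledger([])
    assert all(c.d_exp == 0 for c in bin_exposure(empty))
    with pytest.raises(ValueError):
        bin_exposure(empty, bounds=[13, 13, 25])


@pytest.mark.parametrize(
    "events, d_exp, expected",
    [(7, 5757.0, 0.641), (4, 7763.0, 0.828), (0, 5979.0, 1.0), (1, 4573.0, 0.923)],
)
def test_annual_survival_study_values(events, d_exp, expected):
    est = annual_survival(events, d_exp)
    assert est.period_survival == pytest.approx(expected, abs=5e-4)
    assert est.dsr == 1.0 - est.dmr


def test_annual_survival_rejects_zero_exposure():
    with pytest.raises(ValueError):
        annual_survival(1, 0.0)


def test_johnson_ci_contains_point_and_zero_event_degeneracy():
    lo, hi = johnson_ci(7, 5757.0)
    point = annual_survival(7, 5757.0).period_survival
    assert lo < point < hi
    lo0, hi0 = johnson_ci(0, 5979.0)
    assert hi0 == 1.0 and 0.0 < lo0 < 1.0


def test_johnson_ci_shrinks_with_exposure_at_fixed_rate():
    """Doubling exposure days at the same daily rate halves the variance:
    the delta-method interval must tighten."""
    w1 = np.diff(johnson_ci(4, 4000.0))[0]
    w2 = np.diff(johnson_ci(8, 8000.0))[0]
    assert w2 < w1


def test_pfail_adjusted_lower_cl_monotone_and_noop():
    base_lo = johnson_ci(7, 5757.0)[0]
    adj = pfail_adjusted_lower_cl(8, 7, 5757.0)
    assert adj < base_lo
    same = pfail_adjusted_lower_cl(7, 7, 5757.0)
    assert same == pytest.approx(base_lo, abs=1e-12)


def test_cumulative_survival_study_values():
    ests = [
        estimate_age_class(c)
        for c in (
            type("C", (), {"age_class": cls, "d_exp": d, "n_events_detected": e, "n_events_corrected": None})()
            for (cls, _n, d, e) in ref.EXPOSURE_TABLE
        )
    ]
    c23 = cumulative_survival(ests[:2])
    assert c23.period_survival == pytest.approx(0.531, abs=5e-4)
    c25 = cumulative_survival(ests)
    assert c25.period_survival == pytest.approx(0.491, abs=1e-3)


def test_cumulative_survival_identity_and_gap_rejection():
    ests = [annual_survival(0, 1000.0) for _ in range(3)]
    for e, cls in zip(ests, [(13, 24), (25, 36), (37, 48)]):
        e.age_class = cls
    assert cumulative_survival(ests).period_survival == 1.0
    ests[1].age_class = (26, 36)
    with pytest.raises(ValueError):
        cumulative_survival(ests)


def test_period_survival_monotone_in_events_and_exposure():
    s = annual_survival(5, 6000.0).period_survival
    assert annual_survival(6, 6000.0).period_survival < s
    assert annual_survival(5, 7000.0).period_survival > s


def test_mayfield_recovers_known_survival_on_simulated_cohorts():
    """Pooled over 200 small cohorts with a known annual survival, the
    exposure-day estimator lands within 3 SE of truth."""
    s_true = 0.75
    d_exp = 0.0
    events = 0
    for i in range(200):
        spec = CohortSpec(
            n_animals=50,
            annual_survival_by_ageclass={2: s_true},
            release_age_months=13,
            horizon_months=24,
            rng_seed=2000 + i,
        )
        _a, ledger, _e = simulate_cohort(spec)
        cls = bin_exposure(ledger)[0]
        d_exp += cls.d_exp
        events += cls.n_events_detected
    est = annual_survival(events, d_exp)
    var_dsr = events * (d_exp - events) / d_exp**3
    se_annual = 365.25 * est.dsr**364.25 * np.sqrt(var_dsr)
    assert abs(est.period_survival - s_true) <= 3 * se_annual


def test_cumulative_equals_merged_interval_under_constant_hazard():
    """Splitting a constant-hazard interval into classes and multiplying
    the class survivals equals direct estimation on the merged interval."""
    spec = CohortSpec(
        n_animals=4000,
        annual_survival_by_ageclass={2: 0.7, 3: 0.7},
        release_age_months=13,
        horizon_months=36,
        rng_seed=77,
    )
    _a, ledger, _e = simulate_cohort(spec)
    classes = bin_exposure(ledger, bounds=[13, 25, 37])
    split = [estimate_age_class(c) for c in classes]
    merged = annual_survival(
        sum(c.n_events_detected for c in classes),
        sum(c.d_exp for c in classes),
        period_days=2 * 365.25,
    )
    product = split[0].period_survival * split[1].period_survival
    assert product == pytest.approx(merged.period_survival, rel=5e-3)
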