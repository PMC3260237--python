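"""Vital-rate schedules, natality, population vectors."""

import io

import numpy as np
import pytest

from lhxpop.schedules import (
    N_AGES,
    VitalSchedule,
    build_lhx_egoa,
    calibrate_seed,
    derive_male_schedule,
    load_schedule,
    minimum_natality,
    percentile_age,
    population_vectors,
    set_pp_schedule,
    write_schedules,
)


def _flat_schedule(s=0.8, pp=0.0, sex="female"):
    return VitalSchedule(sex=sex, s=np.full(N_AGES, s), pp=np.full(N_AGES, pp))


def test_partition_identity_holds_after_mutations():
    sched = set_pp_schedule(_flat_schedule(0.7), 0.89)
    assert np.allclose(sched.s + sched.m_p + sched.m_np, 1.0, atol=1e-12)
    male = derive_male_schedule(sched, 0.05)
    assert np.allclose(male.s + male.m_p + male.m_np, 1.0, atol=1e-12)


def test_schedule_round_trip(tmp_path):
    sched = set_pp_schedule(_flat_schedule(0.85), 0.5)
    path = tmp_path / "sched.csv"
    write_schedules([sched], path)
    back = load_schedule(path)
    assert np.allclose(back.s, sched.s) and np.allclose(back.pp, sched.pp)


def test_schedule_validation_names_offending_row():
    sched = _flat_schedule(0.9)
    frame = sched.to_frame()
    frame.loc[frame.age_year == 7, "m_np"] = 0.5  # break the partition
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    buf.seek(0)
    with pytest.raises(ValueError, match="age_year=7"):
        load_schedule(buf)


def test_set_pp_schedule_decay_rule():
    """Young-of-the-year carry 30% of the juvenile share, years 2-5 the full
    share, then a 50%-per-year decay."""
    sched = set_pp_schedule(_flat_schedule(), 0.89)
    assert sched.pp[0] == pytest.approx(0.267, abs=5e-4)
    assert np.allclose(sched.pp[1:5], 0.89)
    assert sched.pp[5] == pytest.approx(0.445, abs=5e-4)
    assert sched.pp[6] == pytest.approx(0.2225, abs=5e-5)
    zero = set_pp_schedule(_flat_schedule(), 0.0)
    assert np.all(zero.m_p == 0.0)


def test_minimum_natality_closed_form_all_survive():
    """With survival 1 everywhere, 17 reproductive year-classes share the
    both-sex seed: natality = 2/17."""
    sched = _flat_schedule(1.0)
    assert minimum_natality(sched).value == pytest.approx(2.0 / 17.0, abs=1e-12)


def test_minimum_natality_anchors(schedules):
    assert minimum_natality(schedules.hfys06["female"]).value == pytest.approx(0.60, abs=5e-3)
    assert minimum_natality(schedules.lhx_egoa_naive["female"]).value == pytest.approx(0.92, abs=5e-3)
    assert minimum_natality(schedules.lhx_egoa["female"]).value == pytest.approx(0.69, abs=5e-3)
    assert minimum_natality(schedules.hfys_pre["female"]).value == pytest.approx(0.63, abs=5e-3)


def test_minimum_natality_invariant_to_male_schedule(schedules):
    female = schedules.lhx_egoa["female"]
    v1 = minimum_natality(female).value
    # male schedule and seed scale do not enter the definition
    _male = derive_male_schedule(female, 0.3)
    assert minimum_natality(female).value == v1


def test_build_lhx_identity_when_nothing_changes(schedules):
    base = schedules.hfys06["female"]
    rebuilt = build_lhx_egoa(
        base,
        {y: float(base.s[y - 1]) for y in (2, 3, 4, 5)},
        pup_rate_year1=float(base.s[0]),
        adult_scale=1.07,
    )
    assert np.allclose(rebuilt.s, base.s, atol=1e-12)


def test_derive_male_schedule_properties(schedules):
    female = schedules.lhx_egoa["female"]
    same = derive_male_schedule(female, 0.0)
    assert np.allclose(same.s, female.s)
    male = derive_male_schedule(female, 0.05)
    ratio = male.s / female.s
    assert np.all(np.diff(ratio[5:]) <= 1e-12)  # non-increasing beyond year 5
    assert np.allclose(ratio[:5], 1.0)


def test_calibrated_sex_specific_age_percentiles(schedules):
    """95% of females within ages 1-19 and males within 1-14."""
    assert percentile_age(schedules.lhx_egoa["female"]) == pytest.approx(19.0, abs=0.35)
    assert percentile_age(schedules.lhx_egoa["male"]) == pytest.approx(14.0, abs=0.35)


def test_population_vectors_geometric_and_conserving():
    sched_f = _flat_schedule(0.5)
    sched_m = _flat_schedule(0.5, sex="male")
    vec = population_vectors(sched_f, sched_m, 100.0)
    expect = 50.0 * 0.5 ** np.arange(N_AGES)
    assert np.allclose(vec.n["female"], expect)
    for sex in ("female", "male"):
        deaths = vec.p[sex].sum() + vec.d[sex].sum()
        assert deaths == pytest.approx(50.0, abs=1e-9)


def test_seed_conservation_exact_on_reference_schedules(schedules):
    vec = population_vectors(schedules.lhx_egoa["female"], schedules.lhx_egoa["male"], 12345.0)
    for sex in ("female", "male"):
        assert vec.p[sex].sum() + vec.d[sex].sum() == pytest.approx(12345.0 / 2, rel=1e-12)


def test_calibrate_seed_linear(schedules):
    f, m = schedules.lhx_egoa["female"], schedules.lhx_egoa["male"]
    assert calibrate_seed(f, m, 0.0) == 0.0
    s1 = calibrate_seed(f, m, 10_000.0)
    s2 = calibrate_seed(f, m, 20_000.0)
    assert s2 == pytest.approx(2 * s1, rel=1e-12)
    assert population_vectors(f, m, s1).total == pytest.approx(10_000.0, rel=1e-9)


def test_juvenile_fraction_responds_to_juvenile_survival(schedules):
    female = schedules.lhx_egoa["female"]
    male = schedules.lhx_egoa["male"]

    def jt(f, m):
        vec = population_vectors(f, m, 1000.0)
        top = sum(v[1:5].sum() for v in vec.n.values())
        bot = sum(v[1:].sum() for v in vec.n.values())
        return top / bot

    def shifted(sched, delta):
        bump = np.where((np.arange(N_AGES) >= 1) & (np.arange(N_AGES) < 5), delta, 0.0)
        return VitalSchedule(sex=sched.sex, s=np.clip(sched.s + bump, 1e-9, 1.0), pp=sched.pp)

    # harder juvenile mortality thins the adult pool more than the juvenile
    # one, so J/T rises monotonically as juvenile survival falls
    vals = [jt(shifted(female, d), shifted(male, d)) for d in (-0.10, -0.05, 0.0)]
    assert all(0.0 < v < 1.0 for v in vals)
    assert vals[0] > vals[1] > vals[2]


def test_pup_survival_plausible_and_scaling_shift(schedules):
    """The naive five-year replacement inflates natality (0.92) and the
    1.13 adult scaling brings it to the observed 0.69."""
    p = schedules.params
    assert 0.4 < p.s1_lhx < 0.9
    assert minimum_natality(schedules.lhx_egoa_naive["female"]).value > minimum_natality(
        schedules.lhx_egoa["female"]
    ).value
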