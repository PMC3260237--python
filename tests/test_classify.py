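"""Cause-of-death classification and the predation-proportion estimate."""

import math
import random

import numpy as np
import pytest

from lhxpop.classify import (
    ClassificationResult,
    CoolingParams,
    MortalityEvent,
    classify_event,
    estimate_pp,
    exact_pp_lower_cl,
    extract_features,
    fit_cooling_mass,
    mc_pp_lower_cl,
)
from lhxpop.synthcohort import generate_temperature_profile


def _event(series, delay=0.0, ambient=8.0, mass=100.0, eid="E1"):
    return MortalityEvent(
        event_id=eid,
        age_at_death_months=20,
        temp_series=np.asarray(series, dtype=float),
        transmission_delay_h=delay,
        ambient_c=ambient,
        expected_mass_kg=mass,
    )


def test_features_step_profile():
    t = np.arange(0, 48.25, 0.25)
    temp = np.where(t < 0.2, 37.0, 8.0)
    f = extract_features(_event(np.column_stack([t, temp])))
    assert f.usable
    assert f.time_to_ambient_h == pytest.approx(0.25, abs=1e-9)
    assert f.transmission_delay_h == 0.0


def test_features_slow_exponential_exceeds_half_day():
    # half-life 6 h: 29 degC above an 8 degC ambient needs ~4.9 half-lives
    # to come within the 1 degC band, i.e. ~29 h
    k = math.log(2) / 6.0
    t = np.arange(0, 48.25, 0.25)
    temp = 8.0 + 29.0 * np.exp(-k * t)
    f = extract_features(_event(np.column_stack([t, temp])))
    assert f.time_to_ambient_h > 12.0


def test_features_degenerate_series_marked_unusable():
    f = extract_features(_event(np.array([[0.0, 37.0]])))
    assert not f.usable
    assert extract_features(_event(np.empty((0, 2)))).usable is False


@pytest.mark.parametrize("frac, tol", [(1.0, 0.05), (0.14, 0.03)])
def test_cooling_mass_round_trip(frac, tol):
    """Profiles generated at a known cooling-mass fraction recover it."""
    series, _d, _m = generate_temperature_profile(
        "non_traumatic", 100.0, 8.0, rng_seed=5, mass_fraction=frac
    )
    fitted = fit_cooling_mass(series, 8.0, 100.0)
    assert fitted == pytest.approx(frac, abs=tol)


def test_cooling_mass_noise_free_exact():
    params = CoolingParams(noise_sd=0.0)
    series, _d, _m = generate_temperature_profile(
        "non_traumatic", 80.0, 10.0, params=params, rng_seed=0, mass_fraction=0.5
    )
    fitted = fit_cooling_mass(series, 10.0, 80.0, params)
    assert fitted == pytest.approx(0.5, rel=1e-4)


def test_classify_three_archetypes():
    # acute step drop with immediate transmissions -> predation
    step, delay, media = generate_temperature_profile("predation", 100.0, 8.0, rng_seed=1)
    r = classify_event(_event(step, delay=delay))
    assert r.cause == "predation" and "acute_drop" in r.rationale_flags
    # gradual cooling at 14% of expected mass -> predation (partial dismemberment)
    small, d2, _ = generate_temperature_profile(
        "non_traumatic", 100.0, 8.0, rng_seed=2, mass_fraction=0.14
    )
    r = classify_event(_event(small, delay=d2))
    assert r.cause == "predation" and "partial_dismemberment" in r.rationale_flags
    assert r.cooling_mass_fraction == pytest.approx(0.14, abs=0.03)
    # gradual cooling at full mass -> non-traumatic
    full, d3, _ = generate_temperature_profile("non_traumatic", 100.0, 8.0, rng_seed=3)
    r = classify_event(_event(full, delay=d3))
    assert r.cause == "non_traumatic"
    # no payload -> undetermined
    r = classify_event(_event(np.empty((0, 2))))
    assert r.cause == "undetermined"


def test_classifier_accuracy_on_synthetic_archetypes():
    """>= 99% of simulated predation and intact non-traumatic events are
    labelled correctly at default thresholds and sensor noise."""
    rng = np.random.default_rng(12)
    correct = total = 0
    for i in range(150):
        mass = float(rng.uniform(30, 160))
        for cause in ("predation", "non_traumatic"):
            series, delay, _m = generate_temperature_profile(cause, mass, 8.0, rng_seed=rng)
            r = classify_event(_event(series, delay=delay, mass=mass))
            total += 1
            correct += r.cause == cause
    assert correct / total >= 0.99


def _results(n_pred, n_nontrauma, n_undet=0):
    out = []
    for i in range(n_pred):
        out.append(ClassificationResult(f"p{i}", "predation"))
    for i in range(n_nontrauma):
        out.append(ClassificationResult(f"n{i}", "non_traumatic"))
    for i in range(n_undet):
        out.append(ClassificationResult(f"u{i}", "undetermined"))
    return out


def test_pp_point_uses_conservative_denominator():
    """11 predation of 11 classified in 12 detected gives the minimum
    proportion 11/12 = 0.917, with the 11/11 ceiling flagged."""
    est = estimate_pp(_results(11, 0, 1), rng_seed=0)
    assert est.pp_point == pytest.approx(11 / 12, abs=1e-12)
    assert est.pp_lower_cl95 == pytest.approx(0.78, abs=0.015)
    assert est.pp_working == pytest.approx(0.89, abs=0.01)
    assert any("1.000" in n for n in est.notes)


def test_pp_zero_predation_and_empty_errors():
    assert estimate_pp(_results(0, 5), rng_seed=0).pp_point == 0.0
    with pytest.raises(ValueError):
        estimate_pp(_results(0, 0, 3), rng_seed=0)


def test_pp_invariant_to_event_order():
    results = _results(7, 2, 1)
    a = estimate_pp(results, rng_seed=4)
    random.Random(0).shuffle(results)
    b = estimate_pp(results, rng_seed=4)
    assert a.pp_point == b.pp_point and a.pp_lower_cl95 == b.pp_lower_cl95


def test_pp_lower_cl_matches_exact_binomial():
    """MC lower CL equals the closed-form CDF inversion to grid resolution."""
    mc = mc_pp_lower_cl(11, 12, iterations=10_000, rng_seed=2)
    exact = exact_pp_lower_cl(11, 12)
    assert exact == pytest.approx(0.05 ** (1 / 12), abs=1e-9)
    assert abs(mc - exact) <= 0.015


def test_pp_lower_cl_monotone_in_predation_count():
    vals = [mc_pp_lower_cl(k, 12, iterations=4000, rng_seed=9) for k in range(0, 13)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_pp_lower_cl_all_predation_approaches_one():
    vals = [mc_pp_lower_cl(n, n, iterations=4000, rng_seed=3) for n in (5, 20, 60)]
    assert vals[0] < vals[1] < vals[2] < 1.0
    assert vals[2] > 0.9
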