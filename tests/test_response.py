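"""Density-dependent numerical responses and the abundance sweep."""

import numpy as np
import pytest

from lhxpop import response as rsp


@pytest.fixture()
def flat_model(anchors, mass_schedules):
    return rsp.ResponseModel(kind="flat", anchors=anchors, mass_schedule=mass_schedules)


@pytest.fixture()
def linear_model(anchors, mass_schedules):
    return rsp.ResponseModel(kind="linear", anchors=anchors, mass_schedule=mass_schedules)


def test_anchor_consumption_shares(anchors):
    """Predation shifts from juvenile-dominated at 20% abundance (pups ~23%,
    juveniles ~72%, adults ~5%) toward adults at 100%."""
    c20 = anchors.consumption_20
    tot = sum(v.sum() for v in c20.values())
    pup = sum(v[0] for v in c20.values()) / tot
    juv = sum(v[1:5].sum() for v in c20.values()) / tot
    ad = sum(v[5:].sum() for v in c20.values()) / tot
    assert pup == pytest.approx(0.23, abs=0.05)
    assert juv == pytest.approx(0.72, abs=0.05)
    assert ad == pytest.approx(0.05, abs=0.03)
    c100 = anchors.consumption_100
    tot100 = sum(v.sum() for v in c100.values())
    ad100 = sum(v[5:].sum() for v in c100.values()) / tot100
    assert ad100 > 0.25  # adults carry a major share at full abundance


def test_anchor_rebuilds_pre_decline_juvenile_survival(anchors, schedules, linear_model):
    """At 100% abundance the projected cumulative survival over years 2-5
    matches the pre-decline schedule (0.64 for ages 13-60 months)."""
    met = rsp.metrics_at(linear_model, 1.0)
    n = rsp._project(met.seed, anchors.m_np, rsp.consumption_at(linear_model, 1.0))[0]
    cum = n["female"][5] / n["female"][1]
    assert cum == pytest.approx(0.64, abs=0.01)


def test_flat_consumption_constant_above_anchor(flat_model):
    a = rsp.consumption_at(flat_model, 0.2)
    b = rsp.consumption_at(flat_model, 1.0)
    for sex in rsp.SEXES:
        assert np.allclose(a[sex], b[sex])


def test_linear_consumption_midpoint(linear_model, anchors):
    mid = rsp.consumption_at(linear_model, 0.6)
    for sex in rsp.SEXES:
        expect = 0.5 * (anchors.consumption_20[sex] + anchors.consumption_100[sex])
        assert np.allclose(mid[sex], expect)


def test_below_anchor_proportional_scaling(flat_model, anchors):
    half = rsp.consumption_at(flat_model, 0.1)
    for sex in rsp.SEXES:
        assert np.allclose(half[sex], 0.5 * anchors.consumption_20[sex])


def test_sigmoid_mass_flat_at_high_abundance(sigmoid_model):
    masses = [rsp.metrics_at(sigmoid_model, a).mass_consumed_t for a in (0.6, 0.8, 1.0)]
    assert max(masses) / min(masses) <= 1.01


def test_contemporary_consumption_level(sigmoid_model):
    """Total annual consumption at 20% abundance (~36,000 animals)
    reproduces the contemporary estimate of ~2,676 sea lions."""
    met = rsp.metrics_at(sigmoid_model, 0.2)
    assert met.total_consumed == pytest.approx(2676.0, rel=0.10)
    assert met.consumed_juveniles == pytest.approx(1938.0, rel=0.10)


def test_sweep_flat_total_constant(flat_model):
    tab = rsp.sweep(flat_model, np.round(np.arange(0.2, 1.01, 0.1), 3))
    assert tab.total_consumed.max() - tab.total_consumed.min() <= 1e-6 * tab.total_consumed.max()


def test_sigmoid_landmarks(sigmoid_sweep):
    """Mid-abundance landmarks: juvenile-consumption peak near 8,240, PP
    maximum near 0.92, J/T peak interior to the 40-50% band."""
    tab = sigmoid_sweep
    sub = tab[tab.abundance_frac >= 0.2]
    juv_peak = sub.consumed_juveniles.max()
    assert juv_peak == pytest.approx(8240.0, rel=0.10)
    a_peak = sub.abundance_frac[sub.consumed_juveniles.idxmax()]
    assert 0.4 <= a_peak <= 0.55
    assert sub.pp_juvenile.max() == pytest.approx(0.92, abs=0.03)
    a_jt = sub.abundance_frac[sub.j_over_t.idxmax()]
    assert 0.35 <= a_jt <= 0.525
    assert sub.j_over_t.max() > sub.j_over_t.iloc[0]
    assert sub.j_over_t.max() > sub.j_over_t.iloc[-1]


def test_sigmoid_recruitment_collapse(sigmoid_sweep):
    """Female recruitment halves between full abundance (~0.51) and the
    mid-abundance trough while adult-female consumption barely moves."""
    tab = sigmoid_sweep[sigmoid_sweep.abundance_frac >= 0.2]
    assert tab.female_recruitment.iloc[-1] == pytest.approx(0.51, abs=0.01)
    assert tab.female_recruitment.min() == pytest.approx(0.23, abs=0.05)
    a_min = tab.abundance_frac[tab.female_recruitment.idxmin()]
    assert 0.3 <= a_min <= 0.55


def test_adult_female_consumption_change_is_small(sigmoid_model, sigmoid_sweep):
    """The fraction of adult females directly consumed changes little
    between full abundance and the recruitment trough."""
    tab = sigmoid_sweep[sigmoid_sweep.abundance_frac >= 0.2]
    a_trough = float(tab.abundance_frac[tab.female_recruitment.idxmin()])

    def frac(a):
        c = rsp.consumption_at(sigmoid_model, a)
        met = rsp.metrics_at(sigmoid_model, a)
        n = rsp._project(met.seed, sigmoid_model.anchors.m_np, c)[0]
        return c["female"][5:].sum() / n["female"][5:].sum()

    assert abs(frac(a_trough) - frac(1.0)) <= 0.03


def test_linear_pup_difference_monotone(linear_model):
    tab = rsp.sweep(linear_model, np.round(np.arange(0.2, 1.01, 0.05), 3))
    diffs = np.diff(tab.pup_difference.to_numpy())
    assert np.all(diffs < 0) or np.all(diffs > 0)


def test_np_mortality_schedule_density_independent(sigmoid_model, anchors):
    """Per-capita non-predation mortality is elementwise identical at every
    abundance — the framework's central density-independence assumption."""
    for a in (0.2, 0.45, 0.8, 1.0):
        met = rsp.metrics_at(sigmoid_model, a)
        n, _c, _d, _ = rsp._project(met.seed, anchors.m_np, rsp.consumption_at(sigmoid_model, a))
        for sex in rsp.SEXES:
            np_deaths = n[sex] * anchors.m_np[sex]
            with np.errstate(invalid="ignore", divide="ignore"):
                percap = np.where(n[sex] > 0, np_deaths / np.where(n[sex] > 0, n[sex], 1.0), 0.0)
            assert np.allclose(percap[n[sex] > 0], anchors.m_np[sex][n[sex] > 0], atol=1e-12)


def test_conservation_at_every_abundance(sigmoid_model, anchors):
    for a in (0.25, 0.5, 0.75, 1.0):
        met = rsp.metrics_at(sigmoid_model, a)
        n, c_eff, d_np, _ = rsp._project(
            met.seed, anchors.m_np, rsp.consumption_at(sigmoid_model, a)
        )
        for sex in rsp.SEXES:
            assert d_np[sex].sum() + c_eff[sex].sum() == pytest.approx(met.seed / 2.0, rel=1e-9)


def test_equilibria_by_response_kind(sigmoid_model, flat_model, linear_model, sigmoid_sweep):
    """Only the sigmoid response stabilises the contemporary 20% state;
    flat and linear responses have no stable equilibrium above it."""
    eq_s = rsp.find_equilibria(sigmoid_sweep)
    stable = [a for a, kind in eq_s if kind == "stable"]
    assert any(abs(a - 0.2) <= 0.01 for a in stable)
    for model in (flat_model, linear_model):
        eqs = rsp.find_equilibria(rsp.sweep(model))
        assert not [a for a, kind in eqs if kind == "stable" and a > 0.21]


def test_equilibrium_shift_with_maximal_natality(sigmoid_model):
    """Raising the birth rate to 1.0 moves the stable equilibrium above the
    contemporary 20% state but nowhere near recovery."""
    import dataclasses

    m = dataclasses.replace(sigmoid_model, birth_rate=1.0)
    eqs = rsp.find_equilibria(rsp.sweep(m))
    stable = [a for a, kind in eqs if kind == "stable"]
    assert stable and 0.2 < stable[0] < 0.45


def test_consumption_rejects_out_of_range_abundance(sigmoid_model):
    with pytest.raises(ValueError):
        rsp.consumption_at(sigmoid_model, 0.0)
    with pytest.raises(ValueError):
        rsp.consumption_at(sigmoid_model, 1.2)
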