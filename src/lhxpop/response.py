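"""Age-structured numerical responses and abundance-sweep metrics.

The framework fixes per-capita non-predation mortality (density
independent) and lets the absolute number of animals consumed by predators
vary with total prey abundance between two anchors: the contemporary state
(20% of peak, 36,000 animals, consumption from the contemporary predation
vectors) and the pre-decline state (100%, 180,000 animals, consumption
solved so total per-capita mortality matches the pre-decline survivorship
schedule).  Three response shapes are swept over abundance:

* ``flat``   — consumption fixed at the 20% level for all fractions >= 0.2;
* ``linear`` — elementwise linear interpolation between the two anchors;
* ``sigmoid``— adult consumption declines along a logistic ramp while pup +
  juvenile consumption is solved to hold the total consumed *mass* at the
  100% level for high abundances, blending smoothly into the 20% anchor
  below the mass-conservation knee.

Below 20% all shapes scale proportionally toward zero (no refuge is
assumed).  At each abundance the pup seed is solved so the projected
population totals the target; from the projected vectors the sweep reports
consumption by age group and mass, survival summaries, the pup difference
(seed minus births at a set birth rate — positive means decline), female
recruitment and the juvenile fraction J/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .schedules import N_AGES, REPRO_CLASSES, VitalSchedule, calibrate_seed, population_vectors

SEXES = ("female", "male")

_PJ = slice(0, 5)  # pups + juveniles: age-years 1-5
_AD = slice(5, N_AGES)  # adults: age-years 6-31


@dataclass
class ResponseAnchors:
    """Consumption and per-capita non-predation mortality at both anchors."""

    consumption_20: dict[str, np.ndarray]
    consumption_100: dict[str, np.ndarray]
    m_np: dict[str, np.ndarray]  # per-capita, terminal year closed
    abundance_20_total: float
    abundance_100_total: float


@dataclass(frozen=True)
class SigmoidParams:
    """Shape of the sigmoid response's adult decline and mass conservation."""

    midpoint: float = 0.6
    steepness: float = 14.0
    knee: float = 0.5  # mass held at the 100% level for fractions >= knee
    blend_power: float = 1.5  # ease-out exponent of the sub-knee blend


@dataclass
class ResponseModel:
    kind: str  # flat | linear | sigmoid
    anchors: ResponseAnchors
    mass_schedule: dict[str, np.ndarray]
    birth_rate: float = 0.69
    pregnancy_mass_increment: float = 0.07  # fraction of body mass
    juvenile_group: tuple[int, int] = (2, 4)  # reporting split (figure style)
    jt_ages: tuple[int, int] = (2, 5)  # J/T numerator ages
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "linear", "sigmoid"):
            raise ValueError(f"unknown response kind {self.kind!r}")

    def effective_mass(self, sex: str) -> np.ndarray:
        """Mass schedule with reproductive females pregnancy-weighted."""
        w = self.mass_schedule[sex].copy()
        if sex == "female":
            lo, hi = REPRO_CLASSES
            w[lo - 1 : hi] *= 1.0 + self.birth_rate * self.pregnancy_mass_increment
        return w


@dataclass
class AbundanceMetrics:
    abundance_frac: float
    seed: float
    total_consumed: float
    consumed_pups: float
    consumed_juveniles: float
    consumed_adults: float
    mass_consumed_t: float
    overall_survival: float
    juvenile_survival: float
    survival_year2: float
    pp_juvenile: float
    pup_difference: float
    natality_min: float
    female_recruitment: float
    j_over_t: float
    clipped: bool


def anchors_from_schedules(
    lhx_egoa: dict[str, VitalSchedule],
    hfys_pre: dict[str, VitalSchedule],
    abundance_20_total: float = 36_000.0,
    abundance_100_total: float = 180_000.0,
) -> ResponseAnchors:
    """Build the two consumption anchors from the schedule pair.

    At 20% the consumption vectors are the contemporary predation vectors.
    At 100%, per-capita predation is solved so the cumulative survival of
    the age blocks 1-5 (per age) and 6-10 (a uniform per-capita add-on per
    sex) matches the pre-decline schedule, holding the contemporary
    non-predation mortality fixed; beyond age 10 per-capita predation keeps
    its (small, vulnerability-decayed) contemporary value.  An infeasible
    block (required consumption < 0) raises; small float negatives clip.
    """
    from scipy.optimize import brentq

    seed20 = calibrate_seed(lhx_egoa["female"], lhx_egoa["male"], abundance_20_total)
    v20 = population_vectors(lhx_egoa["female"], lhx_egoa["male"], seed20)

    m_np = {sex: lhx_egoa[sex].effective_m_np() for sex in SEXES}
    s100: dict[str, np.ndarray] = {}
    for sex in SEXES:
        s_pre = hfys_pre[sex].effective_s()
        s_lhx = lhx_egoa[sex].effective_s()
        s = s_lhx.copy()
        # ages 1-5: total mortality matches the pre-decline schedule per age
        s[:5] = s_pre[:5]
        if np.any(1.0 - s[:5] - m_np[sex][:5] < -1e-9):
            age = int(np.argmin(1.0 - s[:5] - m_np[sex][:5])) + 1
            raise ValueError(
                f"infeasible 100% anchor: block 1-5, {sex} age-year {age} needs negative consumption"
            )
        # ages 6-10: uniform per-capita predation add-on matching the block product
        target = float(np.prod(s_pre[5:10]))
        base = 1.0 - m_np[sex][5:10]

        def block(pi: float) -> float:
            return float(np.prod(np.clip(base - pi, 1e-12, None))) - target

        if block(0.0) < 0.0:
            raise ValueError(f"infeasible 100% anchor: block 6-10 for {sex}")
        pi = brentq(block, 0.0, float(base.min()) - 1e-9, xtol=1e-14)
        s[5:10] = base - pi
        s100[sex] = s

    # population at 100% under the anchored survivorship, seed -> target total
    l = {sex: np.concatenate([[1.0], np.cumprod(s100[sex])[:-1]]) for sex in SEXES}
    unit = sum(l[sex].sum() for sex in SEXES) / 2.0
    seed100 = abundance_100_total / unit
    c100 = {
        sex: np.clip(seed100 / 2.0 * l[sex] * (1.0 - s100[sex] - m_np[sex]), 0.0, None)
        for sex in SEXES
    }
    return ResponseAnchors(
        consumption_20={sex: v20.p[sex].copy() for sex in SEXES},
        consumption_100=c100,
        m_np=m_np,
        abundance_20_total=abundance_20_total,
        abundance_100_total=abundance_100_total,
    )


def _mass_of(model: ResponseModel, consumption: dict[str, np.ndarray]) -> float:
    return sum(float(consumption[sex] @ model.effective_mass(sex)) for sex in SEXES)


def _logistic_ramp(a: float, p: SigmoidParams) -> float:
    """0 at abundance 0.2, 1 at abundance 1, logistic in between."""

    def sig(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-x))

    lo = sig(p.steepness * (0.2 - p.midpoint))
    hi = sig(p.steepness * (1.0 - p.midpoint))
    return (sig(p.steepness * (a - p.midpoint)) - lo) / (hi - lo)


def _sigmoid_consumption(model: ResponseModel, a: float) -> dict[str, np.ndarray]:
    anch = model.anchors
    p = model.sigmoid
    mass_target = _mass_of(model, anch.consumption_100)

    def at(a_: float) -> dict[str, np.ndarray]:
        ramp = _logistic_ramp(a_, p)
        lin = (a_ - 0.2) / 0.8
        out: dict[str, np.ndarray] = {}
        pattern_mass = 0.0
        pattern: dict[str, np.ndarray] = {}
        adult_mass = 0.0
        for sex in SEXES:
            c20, c100 = anch.consumption_20[sex], anch.consumption_100[sex]
            c = np.zeros(N_AGES)
            c[_AD] = c20[_AD] + ramp * (c100[_AD] - c20[_AD])
            adult_mass += float(c[_AD] @ model.effective_mass(sex)[_AD])
            pat = c20[_PJ] + lin * (c100[_PJ] - c20[_PJ])
            pattern[sex] = pat
            pattern_mass += float(pat @ model.effective_mass(sex)[_PJ])
            out[sex] = c
        budget = max(0.0, mass_target - adult_mass)
        scale = budget / pattern_mass if pattern_mass > 0 else 0.0
        for sex in SEXES:
            out[sex][_PJ] = pattern[sex] * scale
        return out

    if a >= p.knee:
        return at(a)
    # ease-out blend from the 20% anchor up to the knee state: positive
    # slope at 0.2 (so the contemporary equilibrium is approached from
    # above), smooth join at the knee
    t = (a - 0.2) / (p.knee - 0.2)
    s = 1.0 - (1.0 - t) ** p.blend_power
    knee_c = at(p.knee)
    out = {}
    for sex in SEXES:
        c20 = anch.consumption_20[sex]
        c = c20 + s * (knee_c[sex] - c20)
        # adults still follow the logistic ramp (it is ~0 near 0.2 anyway)
        c[_AD] = c20[_AD] + _logistic_ramp(a, p) * (
            anch.consumption_100[sex][_AD] - c20[_AD]
        )
        out[sex] = c
    return out


def consumption_at(model: ResponseModel, abundance_frac: float) -> dict[str, np.ndarray]:
    """Absolute per-sex, per-age consumption counts at one abundance."""
    if not 0.0 < abundance_frac <= 1.0:
        raise ValueError("abundance_frac must lie in (0, 1]")
    anch = model.anchors
    if abundance_frac < 0.2:
        scale = abundance_frac / 0.2
        return {sex: anch.consumption_20[sex] * scale for sex in SEXES}
    if model.kind == "flat":
        return {sex: anch.consumption_20[sex].copy() for sex in SEXES}
    if model.kind == "linear":
        w = (abundance_frac - 0.2) / 0.8
        return {
            sex: anch.consumption_20[sex] + w * (anch.consumption_100[sex] - anch.consumption_20[sex])
            for sex in SEXES
        }
    return _sigmoid_consumption(model, abundance_frac)


def _project(
    seed: float, m_np: dict[str, np.ndarray], consumption: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], bool]:
    """Forward cohort recursion with fixed per-capita non-predation mortality
    and absolute predation counts.

    Returns ``(n, effective consumption, non-predation deaths, clipped)``;
    the terminal year is closed, so any year-31 survivors beyond the
    consumed count are folded into the non-predation deaths and per-sex
    conservation ``sum(d_np) + sum(c_eff) == seed/2`` is exact.
    """
    n: dict[str, np.ndarray] = {}
    c_eff: dict[str, np.ndarray] = {}
    d_np: dict[str, np.ndarray] = {}
    clip_total = 0.0
    nominal_total = 0.0
    for sex, mnp in m_np.items():
        ni = np.zeros(N_AGES)
        ci = np.zeros(N_AGES)
        di = np.zeros(N_AGES)
        ni[0] = seed / 2.0
        for i in range(N_AGES):
            avail = ni[i] * (1.0 - mnp[i])
            di[i] = ni[i] - avail
            ci[i] = min(consumption[sex][i], avail)
            clip_total += consumption[sex][i] - ci[i]
            nominal_total += consumption[sex][i]
            if i < N_AGES - 1:
                ni[i + 1] = avail - ci[i]
            else:
                di[i] += avail - ci[i]  # close the terminal year
        n[sex] = ni
        c_eff[sex] = ci
        d_np[sex] = di
    clipped = clip_total > 1e-6 * max(nominal_total, 1.0)
    return n, c_eff, d_np, clipped


def _solve_seed(model: ResponseModel, target_total: float, consumption) -> float:
    anch = model.anchors
    # unclipped recursion is affine in the seed: n_i = alpha_i * seed + beta_i
    alpha_sum = beta_sum = 0.0
    for sex in SEXES:
        mnp = anch.m_np[sex]
        alpha, beta = 0.5, 0.0
        alpha_sum += alpha
        beta_sum += beta
        for i in range(N_AGES - 1):
            alpha *= 1.0 - mnp[i]
            beta = beta * (1.0 - mnp[i]) - consumption[sex][i]
            alpha_sum += alpha
            beta_sum += beta
    seed = (target_total - beta_sum) / alpha_sum
    if seed >= 0.0:
        n, _c, _d, clipped = _project(seed, anch.m_np, consumption)
        total = sum(n[sex].sum() for sex in SEXES)
        if not clipped and abs(total - target_total) <= 1e-6 * max(1.0, target_total):
            return seed
    # clipping engaged somewhere: total(seed) is still monotone, bracket it
    hi = max(abs(seed) * 4.0, 10.0)
    f = lambda s: sum(_project(s, anch.m_np, consumption)[0][sx].sum() for sx in SEXES) - target_total
    while f(hi) < 0.0:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, xtol=1e-9 * max(1.0, target_total)))


def metrics_at(model: ResponseModel, abundance_frac: float) -> AbundanceMetrics:
    """All sweep metrics at one abundance fraction."""
    anch = model.anchors
    target = abundance_frac * anch.abundance_100_total
    consumption = consumption_at(model, abundance_frac)
    seed = _solve_seed(model, target, consumption)
    n, c, d_np, clipped = _project(seed, anch.m_np, consumption)

    jl, jh = model.juvenile_group
    total_consumed = sum(c[s].sum() for s in SEXES)
    consumed_pups = sum(c[s][0] for s in SEXES)
    consumed_juv = sum(c[s][jl - 1 : jh].sum() for s in SEXES)
    consumed_ad = total_consumed - consumed_pups - consumed_juv
    mass_t = _mass_of(model, c) / 1000.0

    def survivors(sex: str) -> np.ndarray:
        out = np.zeros(N_AGES)
        out[:-1] = n[sex][1:]
        return out

    n_all = sum(n[s].sum() for s in SEXES)
    surv_all = sum(survivors(s).sum() for s in SEXES)
    juv_n = sum(n[s][jl - 1 : jh].sum() for s in SEXES)
    juv_surv = sum(survivors(s)[jl - 1 : jh].sum() for s in SEXES)
    np_deaths_juv = sum((n[s] * anch.m_np[s])[1:5].sum() for s in SEXES)
    pred_juv_25 = sum(c[s][1:5].sum() for s in SEXES)
    jt_l, jt_h = model.jt_ages
    jt = sum(n[s][jt_l - 1 : jt_h].sum() for s in SEXES) / sum(n[s][1:].sum() for s in SEXES)

    lo, hi = REPRO_CLASSES
    fem_repro = n["female"][lo - 1 : hi].sum()
    births = model.birth_rate * fem_repro
    return AbundanceMetrics(
        abundance_frac=abundance_frac,
        seed=seed,
        total_consumed=total_consumed,
        consumed_pups=consumed_pups,
        consumed_juveniles=consumed_juv,
        consumed_adults=consumed_ad,
        mass_consumed_t=mass_t,
        overall_survival=surv_all / n_all,
        juvenile_survival=juv_surv / juv_n,
        survival_year2=n["female"][2] / n["female"][1] if n["female"][1] > 0 else float("nan"),
        pp_juvenile=pred_juv_25 / (pred_juv_25 + np_deaths_juv),
        pup_difference=seed - births,
        natality_min=seed / fem_repro,
        female_recruitment=n["female"][4] / n["female"][0],
        j_over_t=jt,
        clipped=clipped,
    )


def sweep(model: ResponseModel, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Metrics over an abundance grid, one row per fraction."""
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0001, 0.025), 4)
    rows = [metrics_at(model, float(a)) for a in grid]
    return pd.DataFrame([r.__dict__ for r in rows])


def find_equilibria(table: pd.DataFrame, tol: float = 1e-6) -> list[tuple[float, str]]:
    """Zero crossings of the pup difference with a stability flag.

    The pup difference is seed minus births: positive means decline.  An
    equilibrium is stable when the difference increases through zero with
    abundance (decline above, growth below).  Plateaus at zero (proportional
    scaling below the 20% anchor) are reported once, at their upper edge,
    classified by the sign just above.
    """
    a = table.abundance_frac.to_numpy()
    y = table.pup_difference.to_numpy()
    scale = max(np.abs(y).max(), 1.0)
    z = np.abs(y) <= tol * scale
    out: list[tuple[float, str]] = []
    for i in range(len(a) - 1):
        if z[i] and z[i + 1]:
            continue
        if z[i] and not z[i + 1]:
            out.append((float(a[i]), "stable" if y[i + 1] > 0 else "unstable"))
        elif y[i] * y[i + 1] < 0:
            root = a[i] + (a[i + 1] - a[i]) * (-y[i]) / (y[i + 1] - y[i])
            out.append((float(root), "stable" if y[i + 1] > y[i] else "unstable"))
    return out


def calibrate_sigmoid(
    anchors: ResponseAnchors,
    mass_schedule: dict[str, np.ndarray],
    birth_rate: float = 0.69,
    juvenile_peak_target: float = 8240.0,
    pp_max_target: float = 0.92,
    total_mid_target: float = 11_300.0,
    recruitment_trough_target: float = 0.23,
) -> SigmoidParams:
    """Grid-calibrate the logistic midpoint/steepness to the published
    mid-abundance landmarks (juvenile-consumption peak, PP maximum near 40%,
    total consumption near 50% abundance, recruitment trough, J/T peak
    inside 40-50%)."""
    best: tuple[float, SigmoidParams] | None = None
    probe = np.round(np.arange(0.25, 1.0001, 0.05), 4)
    for midpoint in (0.45, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75):
      for steepness in (4.0, 6.0, 8.0, 10.0, 14.0, 18.0, 24.0):
        for blend_power in (1.0, 1.5, 2.0):
            params = SigmoidParams(
                midpoint=midpoint, steepness=steepness, blend_power=blend_power
            )
            model = ResponseModel(
                kind="sigmoid",
                anchors=anchors,
                mass_schedule=mass_schedule,
                birth_rate=birth_rate,
                sigmoid=params,
            )
            tab = sweep(model, probe)
            juv_peak = tab.consumed_juveniles.max()
            pp_max = tab.pp_juvenile.max()
            a_ppmax = tab.abundance_frac[tab.pp_juvenile.idxmax()]
            tot_mid = tab.loc[np.isclose(tab.abundance_frac, 0.5), "total_consumed"].iloc[0]
            a_jt = tab.abundance_frac[tab.j_over_t.idxmax()]
            recr_min = tab.female_recruitment.min()
            loss = (
                ((juv_peak - juvenile_peak_target) / juvenile_peak_target) ** 2
                + ((pp_max - pp_max_target) / pp_max_target) ** 2
                + ((tot_mid - total_mid_target) / total_mid_target) ** 2
                + ((recr_min - recruitment_trough_target) / recruitment_trough_target) ** 2
                + 0.25 * ((a_ppmax - 0.4) / 0.4) ** 2
                + (0.0 if 0.35 <= a_jt <= 0.55 else 0.5)
            )
            if best is None or loss < best[0]:
                best = (loss, params)
    assert best is not None
    return best[1]
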