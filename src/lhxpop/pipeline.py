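"""End-to-end analysis pipeline: detection -> classification -> survival ->
schedules -> response, with file-based configuration and report output.

Every stage can run from user-supplied files (return-count CSV, event
JSON-lines, exposure-ledger CSV, schedule CSV) or fall back to the study
inputs in :mod:`lhxpop.reference`.  All randomness is seeded through the
config and the seeds are recorded in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import detection as det
from . import reference as ref
from . import response as rsp
from . import schedules as sch
from . import survival as sv


@dataclass
class AnalysisConfig:
    """Pipeline settings; ``None`` paths mean the packaged study inputs."""

    returns_path: str | None = None
    events_path: str | None = None
    ledger_path: str | None = None
    schedule_path: str | None = None  # base schedule CSV (female rows)
    age_class_bounds: list[int] = field(default_factory=lambda: [13, 25, 37, 49, 61])
    annualization_exponent: float = 365.25
    mc_iterations_detection: int = 2500
    mc_iterations_pp: int = 10_000
    rng_seed: int = 0
    acute_time_to_ambient_h: float = 1.0
    immediate_transmission_h: float = 6.0
    small_mass_fraction: float = 0.5
    response_kind: str = "sigmoid"
    response_grid_step: float = 0.025
    birth_rate: float = ref.BIRTH_RATE_CONTEMPORARY
    abundance_100_total: float = ref.TOTAL_ABUNDANCE_100
    abundance_20_total: float = ref.TOTAL_ABUNDANCE_20

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("returns_path", "events_path", "ledger_path", "schedule_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name}: file not found: {p}")
        if self.response_kind not in ("flat", "linear", "sigmoid"):
            raise ValueError(f"response_kind: unknown kind {self.response_kind!r}")
        if not 0 < self.birth_rate <= 1.5:
            raise ValueError("birth_rate: outside (0, 1.5]")


@dataclass
class RunReport:
    config: AnalysisConfig
    detection: det.DetectionEstimate
    odds_ratios: dict[str, float]
    fisher_p: dict[str, float]
    classification: pd.DataFrame
    pp: cl.PPEstimate
    survival_table: pd.DataFrame
    natality: dict[str, float]
    response_tables: dict[str, pd.DataFrame]
    equilibria: dict[str, list[tuple[float, str]]]

    def summary_lines(self) -> list[str]:
        d = self.detection
        lines = [
            f"config hash {self.config.config_hash}  rng seed {self.config.rng_seed}",
            "-- detection --",
            f"P_fail {d.p_fail:.4f}  P_detect {d.p_detect:.4f}  F {d.f_correction:.4f}",
            f"E_corr {d.e_corr:.2f} (integer {d.e_corr_integer}, 95% ci {d.e_corr_ci95})",
            "-- classification --",
            f"predation {self.pp.n_predation}/{self.pp.n_events} detected "
            f"(PP point {self.pp.pp_point:.3f}, lower CL {self.pp.pp_lower_cl95:.2f}, "
            f"working {self.pp.pp_working:.3f})",
            "-- natality --",
        ]
        lines += [f"{k}: {v:.3f}" for k, v in self.natality.items()]
        for kind, eqs in self.equilibria.items():
            lines.append(f"equilibria[{kind}]: " + (", ".join(f"{a:.3f} ({s})" for a, s in eqs) or "none"))
        return lines


def load_return_counts(path) -> dict[str, det.ReturnCounts]:
    df = pd.read_csv(path)
    return {
        row.stratum: det.ReturnCounts(int(row.n_single), int(row.n_dual), row.stratum)
        for row in df.itertuples()
    }


def load_events(path) -> list[cl.MortalityEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            events.append(
                cl.MortalityEvent(
                    event_id=rec["event_id"],
                    age_at_death_months=rec.get("age_at_death_months", 0.0),
                    temp_series=np.asarray(rec.get("temp_series", []), dtype=float).reshape(-1, 2),
                    medium_series=[tuple(x) for x in rec.get("medium_series", [])],
                    transmission_delay_h=rec.get("transmission_delay_h", 0.0),
                    ambient_c=rec.get("ambient_c", 8.0),
                    expected_mass_kg=rec.get("expected_mass_kg", 100.0),
                )
            )
    return events


def write_events(events: list[cl.MortalityEvent], path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {
                        "event_id": e.event_id,
                        "age_at_death_months": e.age_at_death_months,
                        "temp_series": np.asarray(e.temp_series).tolist(),
                        "medium_series": list(map(list, e.medium_series)),
                        "transmission_delay_h": e.transmission_delay_h,
                        "ambient_c": e.ambient_c,
                        "expected_mass_kg": e.expected_mass_kg,
                    }
                )
                + "\n"
            )


def build_study_events(rng_seed: int = 0) -> list[cl.MortalityEvent]:
    """Synthetic sensor payloads matching the study's event mix: ten acute
    step-drop events, one gradual-cooling event at 14% of expected mass
    (partial dismemberment), one event with no usable payload."""
    from .synthcohort import generate_temperature_profile

    rng = np.random.default_rng(rng_seed)
    ages = [14, 15, 16, 18, 19, 20, 22, 23, 27, 30, 33, 49]
    events: list[cl.MortalityEvent] = []
    for i, age in enumerate(ages[:10]):
        series, delay, media = generate_temperature_profile(
            "predation", 100.0, 8.0, rng_seed=rng
        )
        events.append(
            cl.MortalityEvent(
                event_id=f"EV{i + 1:02d}",
                age_at_death_months=age,
                temp_series=series,
                medium_series=media,
                transmission_delay_h=delay,
                ambient_c=8.0,
                expected_mass_kg=100.0,
            )
        )
    series, delay, media = generate_temperature_profile(
        "non_traumatic", 100.0, 8.0, rng_seed=rng, mass_fraction=0.14
    )
    events.append(
        cl.MortalityEvent(
            event_id="EV11",
            age_at_death_months=ages[10],
            temp_series=series,
            medium_series=media,
            transmission_delay_h=delay,
            ambient_c=8.0,
            expected_mass_kg=100.0,
        )
    )
    events.append(
        cl.MortalityEvent(
            event_id="EV12",
            age_at_death_months=ages[11],
            temp_series=np.empty((0, 2)),
            ambient_c=8.0,
            expected_mass_kg=100.0,
        )
    )
    return events


def allocate_extra_events(classes: list[sv.AgeClassExposure], n_extra: int) -> int | None:
    """Index of the age class receiving the corrected-count surplus: the
    class with the most exposure among classes with detected events."""
    if n_extra <= 0:
        return None
    candidates = [i for i, c in enumerate(classes) if c.n_events_detected > 0]
    if not candidates:
        return None
    return max(candidates, key=lambda i: classes[i].d_exp)


def run_pipeline(config: AnalysisConfig) -> RunReport:
    config.validate()

    # -- detection ---------------------------------------------------------
    if config.returns_path:
        strata = load_return_counts(config.returns_path)
        pooled = strata.get("pooled")
        if pooled is None:
            items = [v for k, v in strata.items() if k in ("live", "carcass")] or list(strata.values())
            pooled = items[0]
            for other in items[1:]:
                pooled = pooled.pooled_with(other)
        live = strata.get("live", ref.RETURNS_LIVE)
        carcass = strata.get("carcass", ref.RETURNS_CARCASS)
        predation = strata.get("predation", ref.RETURNS_PREDATION)
    else:
        pooled, live, carcass, predation = (
            ref.RETURNS_POOLED,
            ref.RETURNS_LIVE,
            ref.RETURNS_CARCASS,
            ref.RETURNS_PREDATION,
        )

    events = load_events(config.events_path) if config.events_path else build_study_events(config.rng_seed)
    detected = len(events)
    detection = det.full_detection_estimate(
        pooled, detected, iterations=config.mc_iterations_detection, rng_seed=config.rng_seed
    )
    odds = {
        "live_vs_carcass": det.odds_ratio([(live.n_single, live.n_dual), (carcass.n_single, carcass.n_dual)]),
        "carcass_vs_predation": det.odds_ratio(
            [(carcass.n_single, carcass.n_dual), (predation.n_single, predation.n_dual)]
        ),
    }
    fisher = {
        "live_vs_carcass": det.fisher_exact_two_tailed(
            [(live.n_single, live.n_dual), (carcass.n_single, carcass.n_dual)]
        ),
        "carcass_vs_predation": det.fisher_exact_two_tailed(
            [(carcass.n_single, carcass.n_dual), (predation.n_single, predation.n_dual)]
        ),
    }

    # -- classification ----------------------------------------------------
    thresholds = cl.ClassifierThresholds(
        acute_time_to_ambient_h=config.acute_time_to_ambient_h,
        immediate_transmission_h=config.immediate_transmission_h,
        small_mass_fraction=config.small_mass_fraction,
    )
    results = [cl.classify_event(e, thresholds) for e in events]
    class_table = pd.DataFrame(
        {
            "event_id": [r.event_id for r in results],
            "cause": [r.cause for r in results],
            "time_to_ambient_h": [r.drop_time_to_ambient_h for r in results],
            "cooling_mass_fraction": [r.cooling_mass_fraction for r in results],
            "flags": ["|".join(sorted(r.rationale_flags)) for r in results],
        }
    )
    pp = cl.estimate_pp(results, iterations=config.mc_iterations_pp, rng_seed=config.rng_seed)

    # -- survival ----------------------------------------------------------
    ledger = sv.load_ledger(config.ledger_path) if config.ledger_path else ref.build_study_ledger()
    classes = sv.bin_exposure(ledger, config.age_class_bounds)
    e_upper_total = detection.e_corr_ci95[1] if detection.e_corr_ci95 else detected
    extra_idx = allocate_extra_events(classes, e_upper_total - detection.e_corr_integer)
    estimates = []
    for i, c in enumerate(classes):
        c.n_events_corrected = float(
            np.floor(detection.f_correction * c.n_events_detected)
        )
        e_up = c.n_events_detected + (1 if i == extra_idx else 0)
        est = sv.estimate_age_class(
            c,
            e_corr_upper=e_up,
            period_days=config.annualization_exponent,
        )
        estimates.append(est)
    rows = []
    for c, est in zip(classes, estimates):
        rows.append(
            {
                "age_class": f"{c.age_class[0]}-{c.age_class[1]}",
                "n_animals": c.n_animals,
                "d_exp": c.d_exp,
                "events": c.n_events_detected,
                "annual_survival": est.period_survival,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
                "ci_method": est.ci_method,
            }
        )
    for upto in (2, 3, 4):
        cum = sv.cumulative_survival(estimates[:upto])
        rows.append(
            {
                "age_class": f"cumulative {classes[0].age_class[0]}-{classes[upto - 1].age_class[1]}",
                "n_animals": classes[0].n_animals,
                "d_exp": sum(c.d_exp for c in classes[:upto]),
                "events": sum(c.n_events_detected for c in classes[:upto]),
                "annual_survival": cum.period_survival,
                "ci_lo": cum.ci95[0],
                "ci_hi": cum.ci95[1],
                "ci_method": cum.ci_method,
            }
        )
    survival_table = pd.DataFrame(rows)

    # -- schedules / natality ---------------------------------------------
    schedules = ref.calibrated()
    if config.schedule_path:
        base_female = sch.load_schedule(config.schedule_path, sex="female")
    else:
        base_female = schedules.hfys06["female"]
    lhx_female = sch.build_lhx_egoa(
        base_female,
        {int(r["age_class"].split("-")[0]) // 12 + 1: r["annual_survival"] for r in rows[:4]},
        pup_rate_year1=schedules.params.s1_lhx,
        adult_scale=ref.ADULT_SCALE_LHX,
        pp_juvenile=pp.pp_working,
    )
    lhx_male = sch.set_pp_schedule(
        sch.derive_male_schedule(lhx_female, schedules.params.male_decay), pp.pp_working
    )
    natality = {
        "hfys06": sch.minimum_natality(base_female).value,
        "lhx_naive": sch.minimum_natality(schedules.lhx_egoa_naive["female"]).value,
        "lhx_egoa": sch.minimum_natality(lhx_female).value,
    }

    # -- response ----------------------------------------------------------
    anchors = rsp.anchors_from_schedules(
        {"female": lhx_female, "male": lhx_male},
        schedules.hfys_pre,
        abundance_20_total=config.abundance_20_total,
        abundance_100_total=config.abundance_100_total,
    )
    mass = {s: ref.mass_schedule(s) for s in rsp.SEXES}
    grid = np.round(np.arange(config.response_grid_step, 1.0 + 1e-9, config.response_grid_step), 6)
    tables: dict[str, pd.DataFrame] = {}
    equilibria: dict[str, list[tuple[float, str]]] = {}
    kinds = [config.response_kind] if config.response_kind else ["flat", "linear", "sigmoid"]
    sigmoid_params = None
    for kind in kinds:
        if kind == "sigmoid" and sigmoid_params is None:
            sigmoid_params = rsp.calibrate_sigmoid(anchors, mass, birth_rate=config.birth_rate)
        model = rsp.ResponseModel(
            kind=kind,
            anchors=anchors,
            mass_schedule=mass,
            birth_rate=config.birth_rate,
            sigmoid=sigmoid_params or rsp.SigmoidParams(),
        )
        tab = rsp.sweep(model, grid)
        tables[kind] = tab
        equilibria[kind] = rsp.find_equilibria(tab)

    return RunReport(
        config=config,
        detection=detection,
        odds_ratios=odds,
        fisher_p=fisher,
        classification=class_table,
        pp=pp,
        survival_table=survival_table,
        natality=natality,
        response_tables=tables,
        equilibria=equilibria,
    )


def write_report(report: RunReport, out_dir, plots: bool = False) -> list[Path]:
    """Write the report tables as CSV plus a plain-text summary; optional
    per-kind sweep plots.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    save(report.classification, "classification.csv")
    save(report.survival_table, "survival_table.csv")
    for kind, tab in report.response_tables.items():
        save(tab, f"response_{kind}.csv")
    summary = out / "summary.txt"
    summary.write_text("\n".join(report.summary_lines()) + "\n")
    written.append(summary)
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for kind, tab in report.response_tables.items():
            fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
            axes[0].plot(tab.abundance_frac, tab.total_consumed)
            axes[0].set_title("animals consumed / yr")
            axes[1].plot(tab.abundance_frac, tab.pup_difference)
            axes[1].axhline(0, color="k", lw=0.5)
            axes[1].set_title("pup difference")
            axes[2].plot(tab.abundance_frac, tab.j_over_t)
            axes[2].set_title("J/T")
            for ax in axes:
                ax.set_xlabel("abundance fraction")
            fig.suptitle(f"{kind} numerical response")
            fig.tight_layout()
            p = out / f"response_{kind}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)
    return written
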