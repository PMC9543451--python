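"""Synthetic pediatric inpatient EHR bundles with controllable DIKI effects.

The generator emulates the statistical structure the pipeline consumes — a
hospitalization table, serum-creatinine (SCr) results, drug administrations
and a drug catalog — with per-drug injected odds ratios so every stage can
be tested against a known truth.

Outcome model.  A latent DIKI event is realized per record from a logistic
model: logit P(event) = logit(baseline) + sum over exposed drugs of
log(true OR) + an optional age term.  Using a logistic outcome makes the
injected OR the exact estimand of the stage-2 analysis.

SCr model.  Baseline results are multiplicative-lognormal noise around the
age/sex median Q, so untreated records are almost always non-triggering.
Event records receive an additional result at a simulated abnormal time T2
(after the start of the earliest drug exposure), and all results from T2 on
are elevated roughly three-fold, which drives eGFR far below its reference
band (and SCr above 130 umol/L in adolescents).  Trajectories are
piecewise-constant; no physiologic kinetics are modelled.

The synthetic presets use the age-valid ("corrected") girls' Q coefficient
set; configuring the printed coefficients together with ages above ~8.5 y
is reported as a configuration error before generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .ehr_data import CodeLists, EHRBundle
from .renal_function import QCoefficients, _q_array

__all__ = [
    "ConfigError",
    "DrugSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_bundle",
    "write_truth",
    "scenario_presets",
]


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class DrugSpec:
    """One formulary entry.

    kind: 'test' (screened drug), 'solvent' (intravenous solvent, threshold
    calibration), 'protectant' (kidney-protecting drug), 'external'
    (topical, excluded from screening) or 'other'.
    exposure_age_slope shifts the exposure log-odds per year of age
    (centered at 9 y) — the confounding knob.
    """

    drug_id: str
    name: str
    atc_code: str = ""
    pharm_class: str = ""
    kind: str = "test"
    exposure_prob: float = 0.1
    true_or: float = 1.0
    exposure_age_slope: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_records: int
    seed: int
    drugs: tuple[DrugSpec, ...] = ()
    age_range: tuple[float, float] = (0.1, 18.0)
    female_frac: float = 0.46
    admission_start: str = "2009-01-01"
    admission_end: str = "2020-12-01"
    stay_log_mean: float = 1.6          # lognormal location of stay length (days)
    stay_log_sd: float = 0.5
    min_stay_days: float = 2.0
    baseline_diki_prob: float = 0.07    # latent event rate with no exposures
    outcome_age_slope: float = 0.0      # log-odds of event per year of age (centered 9 y)
    scr_sigma: float = 0.08             # sd of log SCr noise around Q
    extra_tests_mean: float = 1.5       # tests per stay = 2 + Poisson(this)
    event_scr_log_shift: float = 1.1    # mean log elevation of post-event SCr
    event_scr_log_sd: float = 0.15
    kidney_disease_prev: float = 0.03
    kidney_disease_code: str = "N17.9"
    diagnosis_codes: tuple[str, ...] = (
        "J15.9", "A09.0", "C91.0", "Q21.1", "K35.8", "G40.9", "S06.0", "D61.0",
    )
    diagnosis_probs: tuple[float, ...] | None = None
    q_coefficients: QCoefficients = field(default_factory=QCoefficients.corrected)

    def validate(self) -> None:
        errs = []
        if self.n_records < 0:
            errs.append("n_records must be >= 0")
        if self.seed is None:
            errs.append("seed is mandatory")
        for p_name in ("female_frac", "baseline_diki_prob", "kidney_disease_prev"):
            p = getattr(self, p_name)
            if not (0.0 <= p <= 1.0):
                errs.append(f"{p_name}={p} outside [0, 1]")
        for d in self.drugs:
            if not (0.0 <= d.exposure_prob <= 1.0):
                errs.append(f"drug {d.drug_id}: exposure_prob outside [0, 1]")
            if not (d.true_or > 0):
                errs.append(f"drug {d.drug_id}: true_or must be > 0")
        ids = [d.drug_id for d in self.drugs]
        if len(set(ids)) != len(ids):
            errs.append("duplicate drug_id in formulary")
        lo, hi = self.age_range
        if not (0.0767 <= lo < hi <= 18.0):
            errs.append(f"age_range {self.age_range} outside [28 d, 18 y)")
        else:
            grid = np.linspace(lo, min(hi, 18.0) - 1e-9, 256)
            for sex_name, coefs in (("male", self.q_coefficients.male),
                                    ("female", self.q_coefficients.female)):
                q = np.polynomial.polynomial.polyval(grid, coefs)
                if np.any(q <= 0):
                    age_bad = grid[np.argmax(q <= 0)]
                    errs.append(
                        f"Q polynomial for {sex_name} non-positive from age "
                        f"~{age_bad:.2f} y within age_range {self.age_range}; "
                        "use QCoefficients.corrected() or narrow the range"
                    )
        if errs:
            raise ConfigError("; ".join(errs))

    def code_lists(self) -> CodeLists:
        kinds = lambda k: frozenset(d.drug_id for d in self.drugs if d.kind == k)
        return CodeLists(
            kidney_disease_codes=frozenset({self.kidney_disease_code.split(".")[0]}),
            kidney_protecting_drugs=kinds("protectant"),
            solvent_drugs=kinds("solvent"),
            external_drugs=kinds("external"),
        )


@dataclass
class SyntheticTruth:
    """Ground truth written alongside a bundle for evaluation harnesses."""

    drugs: pd.DataFrame    # drug_id, name, kind, exposure_prob, true_or
    records: pd.DataFrame  # record_id, latent_event, t2, n_exposures


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


_H = pd.Timedelta(hours=1)
_MIN = pd.Timedelta(minutes=1)


def generate_bundle(config: SimulationConfig) -> tuple[EHRBundle, SyntheticTruth]:
    """Generate a validated bundle plus its ground truth, reproducibly."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    empty_cols = {
        "admissions": ["record_id", "patient_id", "age", "sex", "admission_time",
                       "discharge_time", "main_diagnosis", "all_diagnoses"],
        "scr": ["record_id", "report_time", "scr"],
        "admins": ["record_id", "drug_id", "atc_code", "first_time", "last_time"],
    }
    catalog = pd.DataFrame(
        [{"drug_id": d.drug_id, "ingredient": d.name.lower(), "atc_code": d.atc_code,
          "pharm_class": d.pharm_class or d.kind} for d in config.drugs],
        columns=["drug_id", "ingredient", "atc_code", "pharm_class"],
    )
    if n == 0:
        bundle = EHRBundle(
            pd.DataFrame(columns=empty_cols["admissions"]),
            pd.DataFrame(columns=empty_cols["scr"]),
            pd.DataFrame(columns=empty_cols["admins"]),
            catalog, config.code_lists(),
        )
        truth = SyntheticTruth(
            drugs=pd.DataFrame(columns=["drug_id", "name", "kind", "exposure_prob", "true_or"]),
            records=pd.DataFrame(columns=["record_id", "latent_event", "t2", "n_exposures"]),
        )
        return bundle, truth

    record_id = np.array([f"R{i:06d}" for i in range(n)])
    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    age = rng.uniform(config.age_range[0], config.age_range[1], n)
    female = rng.random(n) < config.female_frac
    sex = np.where(female, "female", "male")

    start = pd.Timestamp(config.admission_start)
    end = pd.Timestamp(config.admission_end)
    span_days = (end - start).total_seconds() / 86400.0
    admission = (start + pd.to_timedelta(rng.uniform(0, span_days, n), unit="D")).floor("min")
    stay_days = config.min_stay_days + rng.lognormal(config.stay_log_mean,
                                                     config.stay_log_sd, n)
    discharge = (admission + pd.to_timedelta(stay_days, unit="D")).floor("min")

    if config.diagnosis_probs is not None:
        probs = np.asarray(config.diagnosis_probs, dtype=float)
        probs = probs / probs.sum()
    else:
        probs = None
    main_dx = rng.choice(np.asarray(config.diagnosis_codes), size=n, p=probs)
    kidney = rng.random(n) < config.kidney_disease_prev
    all_dx = np.where(kidney, main_dx + ";" + config.kidney_disease_code, main_dx)

    # first SCr test shortly after admission; all drug exposures start after it
    t1 = admission + pd.to_timedelta(rng.uniform(1.0, 6.0, n), unit="h")
    t1 = pd.DatetimeIndex(t1).floor("min")

    drugs = list(config.drugs)
    log_or = np.array([np.log(d.true_or) for d in drugs])
    exposed = np.zeros((n, len(drugs)), dtype=bool)
    for j, d in enumerate(drugs):
        logit_p = _logit(min(max(d.exposure_prob, 1e-9), 1 - 1e-9)) \
            + d.exposure_age_slope * (age - 9.0)
        exposed[:, j] = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_p))

    eta = _logit(config.baseline_diki_prob) + exposed @ log_or \
        + config.outcome_age_slope * (age - 9.0)
    event = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    # drug administration intervals: start in (t1, discharge - 30 h], 1-3 d long
    admin_rows = []
    limit = discharge - pd.Timedelta(hours=30)
    exp_start = np.empty((n, len(drugs)), dtype="datetime64[ns]")
    exp_start[:] = np.datetime64("NaT")
    for j, d in enumerate(drugs):
        idx = np.flatnonzero(exposed[:, j])
        if idx.size == 0:
            continue
        s = t1[idx] + pd.to_timedelta(rng.uniform(2.0, 20.0, idx.size), unit="h")
        s = pd.DatetimeIndex(np.minimum(s.values, limit[idx].values)).floor("min")
        dur = pd.to_timedelta(rng.uniform(1.0, 3.0, idx.size), unit="D")
        e = pd.DatetimeIndex(
            np.minimum((s + dur).values, (discharge[idx] - _H).values)
        ).floor("min")
        exp_start[idx, j] = s.values
        admin_rows.append(pd.DataFrame({
            "record_id": record_id[idx], "drug_id": d.drug_id,
            "atc_code": d.atc_code, "first_time": s, "last_time": e,
        }))
    drug_admins = (
        pd.concat(admin_rows, ignore_index=True)
        if admin_rows else pd.DataFrame(columns=empty_cols["admins"])
    )

    # abnormal-result time T2 for event records: after the earliest exposure
    if len(drugs):
        sentinel = np.datetime64("2262-01-01")
        filled = np.where(np.isnat(exp_start), sentinel, exp_start)
        earliest = filled.min(axis=1)
        culprit = np.where(exposed.any(axis=1), earliest, np.datetime64("NaT"))
    else:
        culprit = np.full(n, np.datetime64("NaT"))
    culprit = pd.DatetimeIndex(culprit)
    clock0 = pd.DatetimeIndex(np.where(culprit.notna(), culprit.values, t1.values))
    t2 = clock0 + pd.to_timedelta(rng.uniform(6.0, 48.0, n), unit="h")
    t2 = pd.DatetimeIndex(np.minimum(t2.values, (discharge - _H).values)).floor("min")
    t2 = pd.DatetimeIndex(np.where(event, t2.values, np.datetime64("NaT")))

    # SCr schedule: first test at t1, extra tests uniform over the stay,
    # plus the T2 result for event records
    k_extra = rng.poisson(config.extra_tests_mean, n) + 1
    rec_rep = np.repeat(np.arange(n), k_extra)
    span = (discharge[rec_rep] - _MIN - t1[rec_rep]).total_seconds()
    extra_t = t1[rec_rep] + pd.to_timedelta(rng.random(rec_rep.size) * span, unit="s")
    ev_idx = np.flatnonzero(event)
    rec_all = np.concatenate([np.arange(n), rec_rep, ev_idx])
    time_all = pd.DatetimeIndex(np.concatenate([
        t1.values, extra_t.floor("min").values, t2[ev_idx].values,
    ]))

    q = _q_array(age, female, config.q_coefficients)
    t2_per_row = t2[rec_all]
    is_post_event = event[rec_all] & t2_per_row.notna() & (time_all >= t2_per_row)
    noise = rng.normal(0.0, config.scr_sigma, rec_all.size)
    elev = rng.normal(config.event_scr_log_shift, config.event_scr_log_sd, rec_all.size)
    scr_val = q[rec_all] * np.exp(np.where(is_post_event, elev, noise))

    scr_results = pd.DataFrame({
        "record_id": record_id[rec_all],
        "report_time": time_all,
        "scr": np.round(scr_val, 1),
    }).sort_values(["record_id", "report_time"], kind="stable").reset_index(drop=True)

    admissions = pd.DataFrame({
        "record_id": record_id, "patient_id": patient_id,
        "age": np.minimum(np.round(age, 4), 18.0 - 1e-4), "sex": sex,
        "admission_time": admission, "discharge_time": discharge,
        "main_diagnosis": main_dx, "all_diagnoses": all_dx,
    })

    bundle = EHRBundle(admissions, scr_results, drug_admins, catalog, config.code_lists())
    truth = SyntheticTruth(
        drugs=pd.DataFrame([
            {"drug_id": d.drug_id, "name": d.name, "kind": d.kind,
             "exposure_prob": d.exposure_prob, "true_or": d.true_or}
            for d in drugs
        ]),
        records=pd.DataFrame({
            "record_id": record_id,
            "latent_event": event,
            "t2": t2,
            "n_exposures": exposed.sum(axis=1),
        }),
    )
    return bundle, truth


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth.drugs.to_csv(out_dir / "truth.csv", index=False)
    rec = truth.records.copy()
    if len(rec) and pd.api.types.is_datetime64_any_dtype(rec["t2"]):
        rec["t2"] = rec["t2"].dt.strftime("%Y-%m-%dT%H:%M")
    rec.to_csv(out_dir / "truth_records.csv", index=False)


# ---------------------------------------------------------------------------
# scenario presets

#: Injected ORs for the nine screened test drugs in `paper_like`, spanning
#: the 1.0-1.6 range of reported pediatric DIKI signal estimates.
PAPER_LIKE_ORS = (1.61, 1.06, 1.07, 1.35, 1.49, 1.01, 1.36, 1.13, 1.17)
_PAPER_LIKE_EXPOSURE = (0.10, 0.07, 0.08, 0.09, 0.11, 0.13, 0.10, 0.14, 0.09)


def _support_drugs() -> list[DrugSpec]:
    return [
        DrugSpec("SOLV01", "Sodium chloride 0.9%", "B05XA03", "iv solvent",
                 kind="solvent", exposure_prob=0.55),
        DrugSpec("SOLV02", "Glucose 5%", "B05BA03", "iv solvent",
                 kind="solvent", exposure_prob=0.45),
        DrugSpec("PROT01", "Nephroprotectant A", "", "kidney protecting",
                 kind="protectant", exposure_prob=0.02),
        DrugSpec("EXT01", "Topical ointment", "D07AC01", "external",
                 kind="external", exposure_prob=0.06),
    ]


def paper_like(n_records: int = 50_000, seed: int = 0) -> SimulationConfig:
    """Nine screened drugs with injected ORs spanning 1.0-1.6, plus solvents,
    a nephroprotectant and an external drug.

    Test-drug exposure and DIKI risk both rise mildly with age, so crude
    screening ratios of the suspected drugs sit clearly above the solvent
    background (as real trigger tallies do) while matching recovers the
    injected conditional ORs.
    """
    drugs = [
        DrugSpec(f"D{j + 1:02d}", f"Test drug {j + 1:02d}", f"X01AA{j + 1:02d}",
                 "test", kind="test", exposure_prob=_PAPER_LIKE_EXPOSURE[j],
                 true_or=PAPER_LIKE_ORS[j], exposure_age_slope=0.08)
        for j in range(9)
    ] + _support_drugs() + [
        DrugSpec(f"OTH{j:02d}", f"Background drug {j:02d}", f"Y01AB{j:02d}",
                 "other", kind="other", exposure_prob=0.05)
        for j in range(1, 4)
    ]
    return SimulationConfig(n_records=n_records, seed=seed, drugs=tuple(drugs),
                            outcome_age_slope=0.06)


def null_world(n_records: int = 20_000, seed: int = 0) -> SimulationConfig:
    """All injected ORs equal 1: nothing should come out positive beyond chance."""
    drugs = [
        DrugSpec(f"N{j:02d}", f"Null drug {j:02d}", f"Z01AC{j:02d}", "test",
                 kind="test", exposure_prob=p, true_or=1.0)
        for j, p in enumerate((0.08, 0.10, 0.12, 0.14, 0.09, 0.11), start=1)
    ] + _support_drugs()
    return SimulationConfig(n_records=n_records, seed=seed, drugs=tuple(drugs))


def confounded(n_records: int = 40_000, seed: int = 0) -> SimulationConfig:
    """A null drug whose exposure rises with age while DIKI risk also rises
    with age: crudely associated with DIKI, innocent after matching."""
    drugs = [
        DrugSpec("CONF01", "Confounded null drug", "W01AA01", "test",
                 kind="test", exposure_prob=0.12, true_or=1.0,
                 exposure_age_slope=0.15),
        DrugSpec("CLEAN01", "Clean null drug", "W01AB01", "test",
                 kind="test", exposure_prob=0.10, true_or=1.0),
    ] + _support_drugs()
    return SimulationConfig(
        n_records=n_records, seed=seed, drugs=tuple(drugs),
        outcome_age_slope=0.09,
    )


def scenario_presets() -> dict[str, Callable[..., SimulationConfig]]:
    """Named scenario factories: preset(n_records=..., seed=...) -> SimulationConfig."""
    return {
        "null_world": null_world,
        "paper_like": paper_like,
        "confounded": confounded,
    }
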