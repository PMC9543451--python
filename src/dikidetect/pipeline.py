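"""Run orchestration: stage 1 -> stage 2 -> reports, as a reproducible job.

A run is a pure function of (input files, configuration, seed): repeated
runs write identical CSVs.  Outputs land in the configured directory:

- ``stage1_screen.csv``     per-drug tallies (a, b, a/b, suspected flag)
- ``stage1_attrition.csv``  record counts after each screening step
- ``stage2_signals.csv``    per-drug 2x2 counts, OR, 95% CI, p, BH-adjusted
  p and the signal class
- ``forest_plot.csv``       (drug, OR, ci_lo, ci_hi) for plotting
- ``cohort_<drug>.csv``     per-drug cohort membership with covariates
- ``stage2_attrition.csv``, ``matching_diagnostics.csv``
- ``run_manifest.json``     seed, configuration, library versions, config hash

Benjamini-Hochberg adjustment spans exactly the drugs that reached stage-2
estimation in the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ehr_data import EHRBundle, normalize_drug_catalog, read_tables
from .renal_function import QCoefficients, RenalParams
from .signal_stats import (
    DEFAULT_CALIPER,
    DEFAULT_MATCH_RATIO,
    adjust_bh,
    analyze_drug,
)
from .stage1_screening import (
    DEFAULT_MIN_USERS,
    DEFAULT_RATIO_THRESHOLD,
    StageOneResult,
    annotate_scr,
    screen_drugs,
)
from .stage2_cohort import build_cohorts

__all__ = ["RunConfig", "run_stage1", "run_stage2", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from a single YAML file."""

    data_dir: str = "."
    codelists_path: str | None = None
    output_dir: str = "diki_output"
    seed: int = 0
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    min_users: int = DEFAULT_MIN_USERS
    caliper: float = DEFAULT_CALIPER
    match_ratio: int = DEFAULT_MATCH_RATIO
    adjusted_model: bool = True
    diag_prefix_len: int = 3
    group1_window: str = "last_scr"
    egfr_abnormal_direction: str = "both"
    scr_threshold: float = 130.0
    q_coefficient_set: str = "printed"   # 'printed' or 'corrected'
    q_coefficients: dict | None = None   # {'male': [c0..c4], 'female': [c0..c4]}

    def renal_params(self) -> RenalParams:
        if self.q_coefficients is not None:
            coefs = QCoefficients(male=tuple(self.q_coefficients["male"]),
                                  female=tuple(self.q_coefficients["female"]))
        else:
            coefs = (QCoefficients.corrected() if self.q_coefficient_set == "corrected"
                     else QCoefficients.printed())
        return RenalParams(
            coefficients=coefs,
            scr_threshold=self.scr_threshold,
            egfr_abnormal_direction=self.egfr_abnormal_direction,  # type: ignore[arg-type]
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, out: Path, extra: dict) -> None:
    import scipy
    import statsmodels

    manifest = {
        "package": "dikidetect",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    manifest.update(extra)
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _load(cfg: RunConfig) -> tuple[EHRBundle, dict[str, str], pd.DataFrame]:
    bundle, rejects = read_tables(cfg.data_dir, cfg.codelists_path)
    norm = normalize_drug_catalog(bundle.drug_catalog) if len(bundle.drug_catalog) else None
    remap = norm.remap if norm else {}
    for w in (norm.warnings if norm else []):
        logger.warning("catalog: %s", w)
    return bundle, remap, rejects


def run_stage1(
    cfg: RunConfig,
    bundle: EHRBundle | None = None,
    remap: dict[str, str] | None = None,
) -> StageOneResult:
    """Screen drugs and write the stage-1 reports."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle, remap, rejects = _load(cfg)
        if len(rejects):
            rejects.to_csv(out / "rejects.csv", index=False)
    result = screen_drugs(
        bundle,
        renal=cfg.renal_params(),
        remap=remap,
        threshold=cfg.ratio_threshold,
        min_users=cfg.min_users,
        group1_window=cfg.group1_window,
    )
    names = bundle.drug_catalog.set_index("drug_id")
    screen = result.screen.copy()
    screen["drug_name"] = screen["drug_id"].map(names["ingredient"])
    screen["atc_code"] = screen["drug_id"].map(names["atc_code"])
    screen["ratio"] = screen["ratio"].round(2)
    screen[["drug_id", "drug_name", "atc_code", "a", "b", "ratio",
            "suspected", "excluded_from_screen"]].to_csv(
        out / "stage1_screen.csv", index=False)
    result.attrition.to_csv(out / "stage1_attrition.csv", index=False)
    with open(out / "stage1_threshold_report.json", "w", encoding="utf-8") as fh:
        json.dump(result.threshold_report, fh, indent=2)
    return result


def run_stage2(
    cfg: RunConfig,
    suspected: list[str],
    bundle: EHRBundle | None = None,
    remap: dict[str, str] | None = None,
    write_cohorts: bool = True,
) -> pd.DataFrame:
    """Cohorts, matching and signal statistics for the suspected drugs."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle, remap, _ = _load(cfg)
    renal = cfg.renal_params()
    scr_flagged = annotate_scr(bundle, renal)

    admins = bundle.drug_admins[["record_id", "drug_id"]].copy()
    if remap:
        admins["drug_id"] = admins["drug_id"].map(lambda d: remap.get(d, d))

    analyses = []
    skipped = []
    attritions = []
    diag_rows = []
    for i, drug in enumerate(suspected):
        members, attrition = build_cohorts(bundle, drug, scr_flagged, remap)
        attritions.append(attrition)
        n_exp = int(members["exposed"].sum())
        n_une = int((~members["exposed"]).sum())
        if n_exp == 0 or n_une == 0:
            logger.warning("drug %s skipped: empty cohort (exposed=%d unexposed=%d)",
                           drug, n_exp, n_une)
            skipped.append({"drug_id": drug, "reason": "empty_cohort"})
            continue
        if members["outcome"].nunique() < 2:
            logger.warning("drug %s skipped: outcome constant in cohorts", drug)
            skipped.append({"drug_id": drug, "reason": "constant_outcome"})
            continue
        # flag co-exposure to other suspected drugs for sensitivity analyses
        other = admins[admins["drug_id"].isin(set(suspected) - {drug})]
        co = members["record_id"].isin(set(other["record_id"]))
        members = members.assign(co_exposed=co.values)
        drug_seed = int(np.random.SeedSequence((cfg.seed, i)).generate_state(1)[0] % (2**31))
        try:
            analysis = analyze_drug(
                members, drug,
                caliper=cfg.caliper, ratio=cfg.match_ratio,
                adjusted=cfg.adjusted_model,
                diag_prefix_len=cfg.diag_prefix_len, seed=drug_seed,
            )
        except ValueError as exc:
            logger.warning("drug %s skipped: %s", drug, exc)
            skipped.append({"drug_id": drug, "reason": str(exc)})
            continue
        analyses.append(analysis)
        for phase, smd in (("pre", analysis.smd_pre), ("post", analysis.smd_post)):
            for cov in ("age", "sex_male", "admit_years"):
                diag_rows.append({"drug_id": drug, "phase": phase,
                                  "covariate": cov, "smd": float(smd[cov])})
        diag_rows.append({"drug_id": drug, "phase": "post", "covariate": "matched_fraction",
                          "smd": analysis.row.matched_fraction})
        if write_cohorts:
            exp_cols = ["record_id", "exposed", "outcome", "age", "sex",
                        "admission_time", "main_diagnosis", "first_exposure_time",
                        "co_exposed"]
            mm = members[exp_cols].copy()
            for c in ("admission_time", "first_exposure_time"):
                mm[c] = pd.to_datetime(mm[c]).dt.strftime("%Y-%m-%dT%H:%M")
            mm.to_csv(out / f"cohort_{drug}.csv", index=False)

    rows = [a.row for a in analyses]
    if rows:
        padj = adjust_bh([r.p for r in rows])
        for r, pa in zip(rows, padj):
            r.p_adj = float(pa)
    signals = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    signals.to_csv(out / "stage2_signals.csv", index=False)
    if len(signals):
        signals[["drug_id", "or_estimate", "ci_lo", "ci_hi"]].rename(
            columns={"or_estimate": "or"}
        ).to_csv(out / "forest_plot.csv", index=False)
    else:
        pd.DataFrame(columns=["drug_id", "or", "ci_lo", "ci_hi"]).to_csv(
            out / "forest_plot.csv", index=False)
    if attritions:
        pd.concat(attritions, ignore_index=True).to_csv(
            out / "stage2_attrition.csv", index=False)
    pd.DataFrame(diag_rows, columns=["drug_id", "phase", "covariate", "smd"]).to_csv(
        out / "matching_diagnostics.csv", index=False)
    _write_manifest(cfg, out, {
        "suspected_drugs": suspected,
        "analyzed_drugs": [r.drug_id for r in rows],
        "skipped": skipped,
        "bh_family_size": len(rows),
    })
    return signals


def run_all(cfg: RunConfig, bundle: EHRBundle | None = None,
            remap: dict[str, str] | None = None) -> tuple[StageOneResult, pd.DataFrame]:
    """Both stages on one dataset load."""
    if bundle is None:
        bundle, remap, rejects = _load(cfg)
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if len(rejects):
            rejects.to_csv(out / "rejects.csv", index=False)
    stage1 = run_stage1(cfg, bundle, remap)
    signals = run_stage2(cfg, stage1.suspected, bundle, remap)
    return stage1, signals
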