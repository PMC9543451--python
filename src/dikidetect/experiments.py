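"""Replicate studies over synthetic worlds: power, type-I error, confounding.

These drive the simulation-based validation of the two-stage detector:

- `paper_like_replicates`: full pipeline (screen -> cohorts -> matching ->
  OR) on the `paper_like` scenario; a drug counts as detected only when it
  both passes the stage-1 screen and comes out a positive signal.
- `null_world_rates`: stage-2 estimation run directly on the test
  drugs of the `null_world` scenario (under the null no drug passes the
  stage-1 a/b gate, by design — the type-I property concerns stage 2).
- `confounded_contrast`: crude versus propensity-matched OR for a null drug
  whose exposure and outcome both rise with age.

All randomness derives from a single base seed via numpy SeedSequence.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd

from .renal_function import QCoefficients, RenalParams
from .signal_stats import analyze_drug, estimate_or
from .stage1_screening import annotate_scr, screen_drugs
from .stage2_cohort import build_cohorts
from .synthetic_ehr import confounded, generate_bundle, null_world, paper_like

__all__ = [
    "paper_like_replicates",
    "positive_rate",
    "null_world_rates",
    "confounded_contrast",
]

logger = logging.getLogger(__name__)

_RENAL = RenalParams(coefficients=QCoefficients.corrected())


def _sub_seed(base_seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((base_seed, *key)).generate_state(1)[0] % (2**31))


def paper_like_replicates(
    n_records: int = 50_000,
    replicates: int = 20,
    base_seed: int = 0,
    adjusted: bool = True,
) -> pd.DataFrame:
    """One row per (replicate, test drug): screening and signal outcome.

    Columns: replicate, drug_id, true_or, suspected, analyzed, or_estimate,
    ci_lo, ci_hi, p, positive.  Drugs not suspected in a replicate carry
    NaN estimates and positive=False.
    """
    rows = []
    for r in range(replicates):
        cfg = paper_like(n_records=n_records, seed=_sub_seed(base_seed, 0, r))
        bundle, truth = generate_bundle(cfg)
        stage1 = screen_drugs(bundle, renal=_RENAL)
        scr_flagged = annotate_scr(bundle, _RENAL)
        test_drugs = truth.drugs[truth.drugs["kind"] == "test"]
        for _, d in test_drugs.iterrows():
            drug = d["drug_id"]
            rec = {
                "replicate": r, "drug_id": drug, "true_or": d["true_or"],
                "suspected": drug in stage1.suspected, "analyzed": False,
                "or_estimate": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                "p": np.nan, "positive": False,
            }
            if rec["suspected"]:
                members, _ = build_cohorts(bundle, drug, scr_flagged)
                try:
                    res = analyze_drug(
                        members, drug, adjusted=adjusted,
                        seed=_sub_seed(base_seed, 1, r, zlib.crc32(drug.encode()) % 2**16),
                    ).row
                except ValueError as exc:
                    logger.warning("replicate %d drug %s not analyzable: %s", r, drug, exc)
                else:
                    rec.update(analyzed=True, or_estimate=res.or_estimate,
                               ci_lo=res.ci_lo, ci_hi=res.ci_hi, p=res.p,
                               positive=res.signal == "positive")
            rows.append(rec)
        logger.info("paper_like replicate %d/%d done", r + 1, replicates)
    return pd.DataFrame(rows)


def positive_rate(results: pd.DataFrame, or_min: float | None = None,
                  or_max: float | None = None) -> tuple[float, int]:
    """Fraction of drug-replicates flagged positive within a true-OR band."""
    sub = results
    if or_min is not None:
        sub = sub[sub["true_or"] >= or_min]
    if or_max is not None:
        sub = sub[sub["true_or"] <= or_max]
    return (float(sub["positive"].mean()) if len(sub) else float("nan"), int(len(sub)))


def null_world_rates(
    n_records: int = 20_000,
    replicates: int = 20,
    base_seed: int = 0,
    adjusted: bool = True,
) -> dict:
    """Type-I behaviour across (replicate, null test drug) stage-2 analyses.

    Returns the positive-signal rate (95% CI lower bound > 1; nominal 2.5%
    under the null, bounded by the 5% two-sided level) and the CI
    noncoverage rate (CI excludes 1 on either side; nominal 5%).
    """
    n_pos = 0
    n_miss = 0
    n_tot = 0
    for r in range(replicates):
        cfg = null_world(n_records=n_records, seed=_sub_seed(base_seed, 2, r))
        bundle, truth = generate_bundle(cfg)
        scr_flagged = annotate_scr(bundle, _RENAL)
        for drug in truth.drugs.loc[truth.drugs["kind"] == "test", "drug_id"]:
            members, _ = build_cohorts(bundle, drug, scr_flagged)
            try:
                res = analyze_drug(
                    members, drug, adjusted=adjusted,
                    seed=_sub_seed(base_seed, 3, r, zlib.crc32(drug.encode()) % 2**16),
                ).row
            except ValueError:
                continue
            n_tot += 1
            n_pos += res.signal == "positive"
            n_miss += not (res.ci_lo <= 1.0 <= res.ci_hi)
    return {
        "positive_rate": n_pos / n_tot if n_tot else float("nan"),
        "noncoverage_rate": n_miss / n_tot if n_tot else float("nan"),
        "n_tests": n_tot,
    }


def confounded_contrast(
    n_records: int = 40_000,
    replicates: int = 3,
    base_seed: int = 0,
) -> dict:
    """Mean crude and matched OR for the age-confounded null drug.

    Both ORs use the unadjusted (exposure-only) outcome model so that the
    difference isolates what matching achieves.
    """
    crude = []
    matched = []
    for r in range(replicates):
        cfg = confounded(n_records=n_records, seed=_sub_seed(base_seed, 4, r))
        bundle, _ = generate_bundle(cfg)
        scr_flagged = annotate_scr(bundle, _RENAL)
        members, _ = build_cohorts(bundle, "CONF01", scr_flagged)
        crude.append(estimate_or(members, adjusted=False, drug_id="CONF01").or_estimate)
        res = analyze_drug(
            members, "CONF01", adjusted=False,
            seed=_sub_seed(base_seed, 5, r),
        ).row
        matched.append(res.or_estimate)
    return {
        "crude_or_mean": float(np.mean(crude)),
        "matched_or_mean": float(np.mean(matched)),
        "crude_ors": [float(x) for x in crude],
        "matched_ors": [float(x) for x in matched],
        "replicates": replicates,
    }
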