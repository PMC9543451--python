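"""Stage 1: screening drugs suspected of causing kidney injury.

The six-step filter over hospitalization records:

1. keep records with at least two serum-creatinine (SCr) tests;
2. keep records whose initial SCr (and its eGFR) is non-triggering — T1 is
   the report time of that initial test;
3. exclude records carrying any kidney-related diagnosis code; survivors
   without a later abnormal result form group 1;
4. records with a later triggering result form group 2 — T2 is the report
   time of the first such result;
5. extract the deduplicated drugs administered during the observation
   window: [T1, T2] for group 2, [T1, last SCr report] for group 1 (the last
   moment renal status is observed; configurable to discharge);
6. per drug tally a = users with a DIKI event (group 2) and b = all users,
   ratio = a/b; a drug is suspected when ratio > threshold (default 0.10,
   sited just above the intravenous-solvent calibration range) and
   b > min_users (default 2000), both strict.

Window intersection is closed on both ends: an administration [first, last]
counts when first <= window_end and last >= T1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .ehr_data import EHRBundle, records_with_codes
from .renal_function import RenalParams, assess_frame

__all__ = [
    "DEFAULT_RATIO_THRESHOLD",
    "DEFAULT_MIN_USERS",
    "StageOneResult",
    "annotate_scr",
    "assign_groups",
    "extract_window_drugs",
    "tally_ratios",
    "calibrate_threshold",
    "select_suspected",
    "screen_drugs",
]

logger = logging.getLogger(__name__)

DEFAULT_RATIO_THRESHOLD = 0.10
DEFAULT_MIN_USERS = 2000


def annotate_scr(bundle: EHRBundle, renal: RenalParams | None = None) -> pd.DataFrame:
    """SCr results joined to age/sex with trigger flags, sorted by record and time."""
    scr = bundle.scr_results.merge(
        bundle.admissions[["record_id", "age", "sex"]], on="record_id", how="inner"
    )
    scr = assess_frame(scr, renal)
    return scr.sort_values(["record_id", "report_time"], kind="stable").reset_index(drop=True)


def assign_groups(
    bundle: EHRBundle,
    renal: RenalParams | None = None,
    scr_flagged: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply steps 1-4; return (assessments, attrition).

    assessments: record_id, t1, t2 (NaT when no event), has_diki,
    last_scr_time for every record surviving steps 1-3.  T2 is the first
    triggering report strictly after T1.
    """
    scr = annotate_scr(bundle, renal) if scr_flagged is None else scr_flagged
    attrition = [("eligible_records", bundle.n_records)]

    counts = scr.groupby("record_id", sort=False).size()
    multi = counts.index[counts >= 2]
    attrition.append(("ge2_scr_tests", len(multi)))
    scr = scr[scr["record_id"].isin(set(multi))]

    first = scr.groupby("record_id", sort=False).first()
    normal_initial = first.index[~first["diki_trigger"]]
    attrition.append(("initial_result_normal", len(normal_initial)))
    scr = scr[scr["record_id"].isin(set(normal_initial))]
    first = first.loc[normal_initial]

    kidney = records_with_codes(
        bundle.admissions, bundle.code_lists.kidney_disease_codes,
        bundle.code_lists.match_mode,
    )
    keep = [r for r in first.index if not kidney.get(r, False)]
    attrition.append(("no_kidney_disease_code", len(keep)))
    scr = scr[scr["record_id"].isin(set(keep))]
    first = first.loc[keep]

    t1 = first["report_time"]
    last_time = scr.groupby("record_id", sort=False)["report_time"].max()
    later = scr.merge(t1.rename("t1"), left_on="record_id", right_index=True)
    trig = later[later["diki_trigger"] & (later["report_time"] > later["t1"])]
    t2 = trig.groupby("record_id", sort=False)["report_time"].min()

    out = pd.DataFrame({
        "record_id": t1.index,
        "t1": t1.values,
        "last_scr_time": last_time.loc[t1.index].values,
    })
    out["t2"] = out["record_id"].map(t2)
    out["has_diki"] = out["t2"].notna()
    attrition.append(("group2_diki_events", int(out["has_diki"].sum())))
    attrition.append(("group1_no_event", int((~out["has_diki"]).sum())))
    attr_df = pd.DataFrame(attrition, columns=["step", "records_remaining"])
    for step, n in attrition:
        logger.info("stage1 attrition: %s = %d", step, n)
    return out.reset_index(drop=True), attr_df


def extract_window_drugs(
    bundle: EHRBundle,
    assessments: pd.DataFrame,
    remap: dict[str, str] | None = None,
    group1_window: str = "last_scr",
) -> pd.DataFrame:
    """Step 5: deduplicated (record_id, drug_id) exposures inside the window.

    Drug ids are translated through `remap` (catalog normalization) before
    deduplication.  `group1_window` closes the group-1 window at the last
    SCr report ('last_scr', default) or at discharge ('discharge').
    """
    win = assessments[["record_id", "t1", "t2", "has_diki", "last_scr_time"]].copy()
    if group1_window == "discharge":
        disch = bundle.admissions.set_index("record_id")["discharge_time"]
        open_end = win["record_id"].map(disch)
    elif group1_window == "last_scr":
        open_end = win["last_scr_time"]
    else:
        raise ValueError("group1_window must be 'last_scr' or 'discharge'")
    win["window_end"] = win["t2"].fillna(pd.Series(open_end.values, index=win.index))

    admins = bundle.drug_admins[["record_id", "drug_id", "first_time", "last_time"]].copy()
    if remap:
        admins["drug_id"] = admins["drug_id"].map(lambda d: remap.get(d, d))
    merged = admins.merge(win[["record_id", "t1", "window_end"]], on="record_id", how="inner")
    hit = (merged["first_time"] <= merged["window_end"]) & (merged["last_time"] >= merged["t1"])
    exposures = merged.loc[hit, ["record_id", "drug_id"]].drop_duplicates()
    return exposures.reset_index(drop=True)


def tally_ratios(assessments: pd.DataFrame, exposures: pd.DataFrame) -> pd.DataFrame:
    """Step 6 tallies: per drug, b = users, a = users with a DIKI event, ratio = a/b.

    Drugs with b = 0 (no in-window users) simply do not appear.
    """
    ev = assessments.set_index("record_id")["has_diki"]
    exp = exposures.copy()
    exp["has_diki"] = exp["record_id"].map(ev).astype(bool)
    tally = exp.groupby("drug_id").agg(a=("has_diki", "sum"), b=("has_diki", "size"))
    tally["a"] = tally["a"].astype(int)
    tally["b"] = tally["b"].astype(int)
    tally["ratio"] = tally["a"] / tally["b"]
    return tally.reset_index().sort_values(
        ["ratio", "b"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)


def calibrate_threshold(
    screen: pd.DataFrame,
    solvent_ids: Iterable[str],
    default_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> dict:
    """Report the solvent a/b range that anchors the screening threshold.

    Intravenous solvents do not injure kidneys, so their a/b values estimate
    the background event ratio; the operative threshold is a configured
    default sited above that range, not recomputed from it.
    """
    solvent_ids = set(solvent_ids)
    rows = screen[screen["drug_id"].isin(solvent_ids)]
    if len(rows) == 0:
        logger.warning("no solvent rows available; threshold stays at default %.3g",
                       default_threshold)
        return {"n_solvents": 0, "ratio_min": None, "ratio_max": None,
                "threshold": default_threshold}
    return {
        "n_solvents": int(len(rows)),
        "ratio_min": float(rows["ratio"].min()),
        "ratio_max": float(rows["ratio"].max()),
        "threshold": default_threshold,
    }


def select_suspected(
    screen: pd.DataFrame,
    threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_users: int = DEFAULT_MIN_USERS,
    exclude_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Flag suspected drugs: ratio > threshold AND b > min_users (both strict).

    `exclude_ids` (external drugs, solvents) never become suspected. Output
    is sorted by ratio descending; comparisons use unrounded ratios.
    """
    out = screen.copy()
    excl = out["drug_id"].isin(set(exclude_ids))
    out["excluded_from_screen"] = excl
    out["suspected"] = (~excl) & (out["ratio"] > threshold) & (out["b"] > min_users)
    return out.sort_values(
        ["ratio", "b"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)


@dataclass
class StageOneResult:
    assessments: pd.DataFrame
    attrition: pd.DataFrame
    screen: pd.DataFrame
    threshold_report: dict
    suspected: list[str] = field(default_factory=list)


def screen_drugs(
    bundle: EHRBundle,
    renal: RenalParams | None = None,
    remap: dict[str, str] | None = None,
    threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_users: int = DEFAULT_MIN_USERS,
    group1_window: str = "last_scr",
    scr_flagged: pd.DataFrame | None = None,
) -> StageOneResult:
    """Run the full stage-1 screen and return tallies + suspected list."""
    cl = bundle.code_lists if remap is None else bundle.code_lists.remapped(remap)
    assessments, attrition = assign_groups(bundle, renal, scr_flagged)
    exposures = extract_window_drugs(bundle, assessments, remap, group1_window)
    screen = tally_ratios(assessments, exposures)
    report = calibrate_threshold(screen, cl.solvent_drugs, threshold)
    screen = select_suspected(
        screen, report["threshold"], min_users,
        exclude_ids=cl.solvent_drugs | cl.external_drugs,
    )
    suspected = screen.loc[screen["suspected"], "drug_id"].tolist()
    logger.info("stage1: %d drugs tallied, %d suspected", len(screen), len(suspected))
    return StageOneResult(assessments, attrition, screen, report, suspected)
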