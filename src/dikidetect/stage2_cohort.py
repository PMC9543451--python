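"""Stage 2: per-drug exposed/unexposed retrospective cohorts.

For each suspected drug the exposed cohort is built from records that
received it and the unexposed cohort from records that never did, each
through five rules:

exposed — (1) received the drug; (2) at least one SCr test strictly before
and one strictly after the first administration; (3) the latest
pre-administration SCr/eGFR is non-triggering (the most proximal baseline);
(4) no kidney-disease diagnosis code; (5) nephroprotectant rule: when a
post-administration trigger exists, no kidney-protecting drug started before
the first abnormal report time; when none exists, no kidney-protecting drug
at any point of the stay.  Outcome = any trigger after first administration.

unexposed — (1) never received the drug; (2) at least two SCr tests;
(3) the initial SCr/eGFR after admission is non-triggering; (4) and (5) as
above, with the observation clock starting at the initial test.  Outcome =
any trigger after the initial test.

Outcome ascertainment ends at discharge; there is no post-discharge
follow-up in the data model.  Records exposed to several suspected drugs
stay in each drug's exposed cohort (drugs are analyzed one at a time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ehr_data import EHRBundle, records_with_codes

__all__ = ["CohortAttrition", "build_exposed", "build_unexposed", "build_cohorts"]

logger = logging.getLogger(__name__)

MEMBER_COLUMNS = [
    "record_id", "exposed", "outcome", "age", "sex",
    "admission_time", "main_diagnosis", "first_exposure_time",
]


@dataclass
class CohortAttrition:
    drug_id: str
    exposed: bool
    steps: list[tuple[str, int]]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.steps, columns=["rule", "records_remaining"])
        df.insert(0, "drug_id", self.drug_id)
        df.insert(1, "arm", "exposed" if self.exposed else "unexposed")
        return df


def _protectant_admins(bundle: EHRBundle, remap: dict[str, str] | None) -> pd.DataFrame:
    admins = bundle.drug_admins[["record_id", "drug_id", "first_time"]].copy()
    if remap:
        admins["drug_id"] = admins["drug_id"].map(lambda d: remap.get(d, d))
    prot_ids = bundle.code_lists.kidney_protecting_drugs
    if remap:
        prot_ids = bundle.code_lists.remapped(remap).kidney_protecting_drugs
    return admins[admins["drug_id"].isin(prot_ids)]


def _apply_protectant_rule(
    members: pd.DataFrame, prot: pd.DataFrame
) -> pd.Series:
    """Boolean keep-mask for rule 5 given members with first_abnormal_time (NaT ok)."""
    prot_first = prot.groupby("record_id")["first_time"].min()
    prot_any = members["record_id"].isin(prot_first.index)
    prot_time = members["record_id"].map(prot_first)
    has_abn = members["first_abnormal_time"].notna()
    # with an abnormality: drop if a protectant started before the first abnormal report
    drop_abn = has_abn & prot_any & (prot_time < members["first_abnormal_time"])
    # without: drop if any protectant during the stay
    drop_clean = ~has_abn & prot_any
    return ~(drop_abn | drop_clean)


def _finalize(members: pd.DataFrame, bundle: EHRBundle, exposed: bool) -> pd.DataFrame:
    cov = bundle.admissions[["record_id", "age", "sex", "admission_time", "main_diagnosis"]]
    out = members.merge(cov, on="record_id", how="left")
    out["exposed"] = exposed
    out["outcome"] = out["first_abnormal_time"].notna()
    if "first_exposure_time" not in out.columns:
        out["first_exposure_time"] = pd.NaT
    return out[MEMBER_COLUMNS + ["first_abnormal_time"]].reset_index(drop=True)


def build_exposed(
    bundle: EHRBundle,
    drug_id: str,
    scr_flagged: pd.DataFrame,
    remap: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, CohortAttrition]:
    """Exposed cohort for one suspected drug (see module docstring for rules).

    `scr_flagged` is the annotated SCr table from
    :func:`dikidetect.stage1_screening.annotate_scr`.
    """
    admins = bundle.drug_admins[["record_id", "drug_id", "first_time"]].copy()
    if remap:
        admins["drug_id"] = admins["drug_id"].map(lambda d: remap.get(d, d))
    steps: list[tuple[str, int]] = []

    first_exp = (
        admins[admins["drug_id"] == drug_id]
        .groupby("record_id")["first_time"].min()
        .rename("first_exposure_time")
    )
    steps.append(("received_drug", len(first_exp)))

    tests = scr_flagged[scr_flagged["record_id"].isin(first_exp.index)].copy()
    tests["first_exposure_time"] = tests["record_id"].map(first_exp)
    before = tests[tests["report_time"] < tests["first_exposure_time"]]
    after = tests[tests["report_time"] > tests["first_exposure_time"]]
    has_both = first_exp.index.intersection(before["record_id"].unique()).intersection(
        after["record_id"].unique()
    )
    steps.append(("scr_before_and_after_medication", len(has_both)))

    baseline = (
        before[before["record_id"].isin(has_both)]
        .sort_values(["record_id", "report_time"], kind="stable")
        .groupby("record_id")
        .last()
    )
    ok_baseline = baseline.index[~baseline["diki_trigger"]]
    steps.append(("baseline_normal_before_medication", len(ok_baseline)))

    kidney = records_with_codes(
        bundle.admissions, bundle.code_lists.kidney_disease_codes,
        bundle.code_lists.match_mode,
    )
    keep = [r for r in ok_baseline if not kidney.get(r, False)]
    steps.append(("no_kidney_disease_code", len(keep)))

    members = pd.DataFrame({"record_id": keep})
    members["first_exposure_time"] = members["record_id"].map(first_exp)
    abn = after[after["diki_trigger"] & after["record_id"].isin(keep)]
    first_abn = abn.groupby("record_id")["report_time"].min()
    members["first_abnormal_time"] = members["record_id"].map(first_abn)

    keep_mask = _apply_protectant_rule(members, _protectant_admins(bundle, remap))
    members = members[keep_mask]
    steps.append(("nephroprotectant_rule", len(members)))

    out = _finalize(members, bundle, exposed=True)
    return out, CohortAttrition(drug_id, True, steps)


def build_unexposed(
    bundle: EHRBundle,
    drug_id: str,
    scr_flagged: pd.DataFrame,
    remap: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, CohortAttrition]:
    """Unexposed cohort: symmetric construction on never-exposed records."""
    admins = bundle.drug_admins[["record_id", "drug_id"]].copy()
    if remap:
        admins["drug_id"] = admins["drug_id"].map(lambda d: remap.get(d, d))
    steps: list[tuple[str, int]] = []

    exposed_ids = set(admins.loc[admins["drug_id"] == drug_id, "record_id"])
    all_ids = bundle.admissions["record_id"]
    unexposed = all_ids[~all_ids.isin(exposed_ids)]
    steps.append(("never_received_drug", len(unexposed)))

    tests = scr_flagged[scr_flagged["record_id"].isin(set(unexposed))]
    counts = tests.groupby("record_id", sort=False).size()
    multi = counts.index[counts >= 2]
    steps.append(("ge2_scr_tests", len(multi)))
    tests = tests[tests["record_id"].isin(set(multi))]

    first = tests.groupby("record_id", sort=False).first()
    ok_initial = first.index[~first["diki_trigger"]]
    steps.append(("initial_result_normal", len(ok_initial)))

    kidney = records_with_codes(
        bundle.admissions, bundle.code_lists.kidney_disease_codes,
        bundle.code_lists.match_mode,
    )
    keep = [r for r in ok_initial if not kidney.get(r, False)]
    steps.append(("no_kidney_disease_code", len(keep)))

    t1 = first.loc[keep, "report_time"]
    later = tests[tests["record_id"].isin(keep)].merge(
        t1.rename("t1"), left_on="record_id", right_index=True
    )
    abn = later[later["diki_trigger"] & (later["report_time"] > later["t1"])]
    first_abn = abn.groupby("record_id")["report_time"].min()

    members = pd.DataFrame({"record_id": keep})
    members["first_abnormal_time"] = members["record_id"].map(first_abn)
    keep_mask = _apply_protectant_rule(members, _protectant_admins(bundle, remap))
    members = members[keep_mask]
    steps.append(("nephroprotectant_rule", len(members)))

    out = _finalize(members, bundle, exposed=False)
    return out, CohortAttrition(drug_id, False, steps)


def build_cohorts(
    bundle: EHRBundle,
    drug_id: str,
    scr_flagged: pd.DataFrame,
    remap: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both arms stacked into one member table, plus the per-rule attrition log."""
    exp, att_e = build_exposed(bundle, drug_id, scr_flagged, remap)
    une, att_u = build_unexposed(bundle, drug_id, scr_flagged, remap)
    members = pd.concat([exp, une], ignore_index=True)
    attrition = pd.concat([att_e.frame(), att_u.frame()], ignore_index=True)
    logger.info(
        "cohorts for %s: %d exposed (%d events), %d unexposed (%d events)",
        drug_id, len(exp), int(exp["outcome"].sum()), len(une), int(une["outcome"].sum()),
    )
    return members, attrition
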