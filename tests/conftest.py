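import pandas as pd
import pytest

from dikidetect.ehr_data import CodeLists, validate_bundle


def make_bundle(admissions, scr_results, drug_admins, drug_catalog=None,
                code_lists=None):
    """Build a validated bundle from lists of row dicts (times as ISO strings)."""
    adm = pd.DataFrame(admissions)
    scr = pd.DataFrame(scr_results, columns=["record_id", "report_time", "scr"])
    dr = pd.DataFrame(drug_admins,
                      columns=["record_id", "drug_id", "atc_code", "first_time", "last_time"])
    if drug_catalog is None:
        ids = sorted(set(dr["drug_id"])) if len(dr) else ["DX1"]
        drug_catalog = [{"drug_id": d, "ingredient": d.lower(), "atc_code": "",
                         "pharm_class": ""} for d in ids]
    cat = pd.DataFrame(drug_catalog,
                       columns=["drug_id", "ingredient", "atc_code", "pharm_class"])
    bundle, rejects = validate_bundle(adm, scr, dr, cat, code_lists or CodeLists())
    return bundle, rejects


def adm_row(record_id, age=5.0, sex="male", admission="2019-01-01T08:00",
            discharge="2019-01-10T10:00", main="J15.9", all_dx=None,
            patient=None):
    return {
        "record_id": record_id, "patient_id": patient or f"P-{record_id}",
        "age": age, "sex": sex, "admission_time": admission,
        "discharge_time": discharge, "main_diagnosis": main,
        "all_diagnoses": all_dx if all_dx is not None else main,
    }


@pytest.fixture
def tiny_bundle():
    """Three eligible admissions with a handful of tests and one drug."""
    bundle, rejects = make_bundle(
        admissions=[adm_row("R1"), adm_row("R2", age=0.5, sex="female"),
                    adm_row("R3", age=12.0)],
        scr_results=[
            ("R1", "2019-01-01T10:00", 35.0),
            ("R1", "2019-01-05T10:00", 36.0),
            ("R2", "2019-01-02T09:00", 20.0),
            ("R3", "2019-01-03T09:00", 55.0),
        ],
        drug_admins=[("R1", "DRG1", "N05BA01", "2019-01-02T08:00", "2019-01-03T08:00")],
    )
    assert len(rejects) == 0
    return bundle


@pytest.fixture(scope="session")
def small_world():
    """A modest paper-like synthetic world shared (read-only) across tests."""
    from dikidetect.renal_function import QCoefficients, RenalParams
    from dikidetect.synthetic_ehr import generate_bundle, paper_like

    bundle, truth = generate_bundle(paper_like(n_records=3000, seed=123))
    renal = RenalParams(coefficients=QCoefficients.corrected())
    return bundle, truth, renal
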