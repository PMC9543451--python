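"""Stage-1 screening: group assignment, drug windows, tallies, thresholding."""

import numpy as np
import pandas as pd
import pytest

from dikidetect.ehr_data import CodeLists
from dikidetect.stage1_screening import (
    annotate_scr,
    assign_groups,
    calibrate_threshold,
    extract_window_drugs,
    screen_drugs,
    select_suspected,
    tally_ratios,
)
from tests.conftest import adm_row, make_bundle

NORMAL = 36.0   # ~Q for a 5-year-old boy -> eGFR in band
HIGH = 60.0     # eGFR ~65, below the 83 floor -> trigger


@pytest.fixture
def screening_bundle():
    """Hand-enumerated records covering every screening step."""
    admissions = [
        adm_row("S1"),                                       # one test: out at step 1
        adm_row("S2"),                                       # initial abnormal: out at step 2
        adm_row("S3", all_dx="J15.9;N17.9"),                 # kidney code: out at step 3
        adm_row("S4"),                                       # group 1
        adm_row("S5"),                                       # group 2
        adm_row("S6"),                                       # group 2, two abnormal results
    ]
    scr = [
        ("S1", "2019-01-02T08:00", NORMAL),
        ("S2", "2019-01-02T08:00", 140.0), ("S2", "2019-01-04T08:00", NORMAL),
        ("S3", "2019-01-02T08:00", NORMAL), ("S3", "2019-01-04T08:00", NORMAL),
        ("S4", "2019-01-02T08:00", NORMAL), ("S4", "2019-01-06T08:00", NORMAL),
        ("S5", "2019-01-02T08:00", NORMAL), ("S5", "2019-01-05T08:00", HIGH),
        ("S5", "2019-01-07T08:00", NORMAL),
        ("S6", "2019-01-02T08:00", NORMAL), ("S6", "2019-01-04T08:00", HIGH),
        ("S6", "2019-01-06T08:00", HIGH),
    ]
    admins = [
        # in-window for S4 (group 1 window = [t1, last test])
        ("S4", "DRGA", "", "2019-01-03T08:00", "2019-01-04T08:00"),
        # before t1 for S4: excluded
        ("S4", "DRGB", "", "2019-01-01T09:00", "2019-01-02T07:00"),
        # in-window for S5 (before t2)
        ("S5", "DRGA", "", "2019-01-03T08:00", "2019-01-04T08:00"),
        # entirely after t2 for S5: excluded
        ("S5", "DRGB", "", "2019-01-06T08:00", "2019-01-06T20:00"),
        # straddles t1 for S6: intersects window
        ("S6", "DRGC", "", "2019-01-01T12:00", "2019-01-02T12:00"),
        # duplicate administration of the same drug in window: counted once
        ("S6", "DRGC", "", "2019-01-03T00:00", "2019-01-03T12:00"),
    ]
    bundle, rejects = make_bundle(
        admissions, scr, admins,
        code_lists=CodeLists(kidney_disease_codes=frozenset({"N17"})),
    )
    assert len(rejects) == 0
    return bundle


class TestAssignGroups:
    def test_matches_hand_enumeration(self, screening_bundle):
        assessments, attrition = assign_groups(screening_bundle)
        byid = assessments.set_index("record_id")
        assert set(byid.index) == {"S4", "S5", "S6"}
        assert not byid.loc["S4", "has_diki"]
        assert byid.loc["S5", "has_diki"]
        assert byid.loc["S5", "t2"] == pd.Timestamp("2019-01-05T08:00")
        assert byid.loc["S6", "t2"] == pd.Timestamp("2019-01-04T08:00")  # first abnormal
        assert (byid["t1"] == pd.Timestamp("2019-01-02T08:00")).all()

    def test_attrition_counts_and_monotonicity(self, screening_bundle):
        _, attrition = assign_groups(screening_bundle)
        steps = dict(zip(attrition["step"], attrition["records_remaining"]))
        assert steps["eligible_records"] == 6
        assert steps["ge2_scr_tests"] == 5
        assert steps["initial_result_normal"] == 4
        assert steps["no_kidney_disease_code"] == 3
        assert steps["group2_diki_events"] == 2
        funnel = attrition["records_remaining"].iloc[:4]
        assert (funnel.diff().dropna() <= 0).all()


class TestWindowExtraction:
    def test_matches_hand_enumeration(self, screening_bundle):
        assessments, _ = assign_groups(screening_bundle)
        exposures = extract_window_drugs(screening_bundle, assessments)
        got = set(map(tuple, exposures[["record_id", "drug_id"]].to_numpy()))
        assert got == {("S4", "DRGA"), ("S5", "DRGA"), ("S6", "DRGC")}

    def test_matches_interval_overlap_oracle(self, screening_bundle):
        assessments, _ = assign_groups(screening_bundle)
        exposures = extract_window_drugs(screening_bundle, assessments)
        win = assessments.set_index("record_id")
        expected = set()
        for _, row in screening_bundle.drug_admins.iterrows():
            rid = row["record_id"]
            if rid not in win.index:
                continue
            t1 = win.loc[rid, "t1"]
            end = win.loc[rid, "t2"] if win.loc[rid, "has_diki"] else win.loc[rid, "last_scr_time"]
            if row["first_time"] <= end and row["last_time"] >= t1:
                expected.add((rid, row["drug_id"]))
        assert set(map(tuple, exposures[["record_id", "drug_id"]].to_numpy())) == expected

    def test_discharge_window_variant_is_wider(self, screening_bundle):
        assessments, _ = assign_groups(screening_bundle)
        narrow = extract_window_drugs(screening_bundle, assessments, group1_window="last_scr")
        wide = extract_window_drugs(screening_bundle, assessments, group1_window="discharge")
        assert len(wide) >= len(narrow)


class TestTally:
    def test_counts_match_hand_recount(self, screening_bundle):
        assessments, _ = assign_groups(screening_bundle)
        exposures = extract_window_drugs(screening_bundle, assessments)
        screen = tally_ratios(assessments, exposures).set_index("drug_id")
        assert screen.loc["DRGA", "a"] == 1 and screen.loc["DRGA", "b"] == 2
        assert screen.loc["DRGA", "ratio"] == pytest.approx(0.5)
        assert screen.loc["DRGC", "a"] == 1 and screen.loc["DRGC", "b"] == 1
        assert "DRGB" not in screen.index  # zero in-window users -> omitted

    def test_zero_events_gives_zero_ratio(self):
        assessments = pd.DataFrame({
            "record_id": ["R1", "R2"],
            "t1": pd.to_datetime(["2019-01-01", "2019-01-01"]),
            "t2": [pd.NaT, pd.NaT],
            "has_diki": [False, False],
            "last_scr_time": pd.to_datetime(["2019-01-05", "2019-01-05"]),
        })
        exposures = pd.DataFrame({"record_id": ["R1", "R2"], "drug_id": ["D", "D"]})
        screen = tally_ratios(assessments, exposures)
        assert screen["ratio"].iloc[0] == 0.0

    def test_invariant_a_le_b_on_synthetic_world(self, small_world):
        bundle, _, renal = small_world
        result = screen_drugs(bundle, renal=renal)
        assert (result.screen["a"] <= result.screen["b"]).all()
        assert (result.screen["b"] > 0).all()

    def test_row_order_invariance(self, small_world):
        bundle, _, renal = small_world
        base = screen_drugs(bundle, renal=renal).screen
        import copy
        shuffled = copy.copy(bundle)
        rng = np.random.default_rng(5)
        shuffled.scr_results = bundle.scr_results.sample(frac=1, random_state=7).reset_index(drop=True)
        shuffled.drug_admins = bundle.drug_admins.sample(frac=1, random_state=8).reset_index(drop=True)
        again = screen_drugs(shuffled, renal=renal).screen
        pd.testing.assert_frame_equal(base, again)

    def test_removing_a_record_never_increases_tallies(self, small_world):
        bundle, _, renal = small_world
        import copy
        base = screen_drugs(bundle, renal=renal).screen.set_index("drug_id")
        victim = bundle.drug_admins["record_id"].iloc[0]
        sub = copy.copy(bundle)
        sub.admissions = bundle.admissions[bundle.admissions["record_id"] != victim]
        sub.scr_results = bundle.scr_results[bundle.scr_results["record_id"] != victim]
        sub.drug_admins = bundle.drug_admins[bundle.drug_admins["record_id"] != victim]
        smaller = screen_drugs(sub, renal=renal).screen.set_index("drug_id")
        joined = base.join(smaller, rsuffix="_sub", how="left").fillna(0)
        assert (joined["a_sub"] <= joined["a"]).all()
        assert (joined["b_sub"] <= joined["b"]).all()


class TestThreshold:
    def test_solvent_range_reported(self):
        screen = pd.DataFrame({
            "drug_id": ["S1", "S2", "D1"],
            "a": [81, 95, 300], "b": [1000, 1000, 1000],
            "ratio": [0.081, 0.095, 0.30],
        })
        rep = calibrate_threshold(screen, {"S1", "S2"})
        assert rep["ratio_min"] == pytest.approx(0.081)
        assert rep["ratio_max"] == pytest.approx(0.095)
        assert rep["threshold"] == 0.10

    def test_single_solvent(self):
        screen = pd.DataFrame({"drug_id": ["S1"], "a": [5], "b": [100], "ratio": [0.05]})
        rep = calibrate_threshold(screen, {"S1"})
        assert rep["ratio_min"] == rep["ratio_max"] == pytest.approx(0.05)

    def test_no_solvents_falls_back_with_default(self):
        screen = pd.DataFrame({"drug_id": ["D1"], "a": [5], "b": [100], "ratio": [0.05]})
        rep = calibrate_threshold(screen, set())
        assert rep["n_solvents"] == 0 and rep["threshold"] == 0.10

    def test_range_matches_minmax_oracle(self):
        rng = np.random.default_rng(6)
        ratios = rng.uniform(0.01, 0.2, 7)
        screen = pd.DataFrame({"drug_id": [f"S{i}" for i in range(7)],
                               "a": 1, "b": 1, "ratio": ratios})
        rep = calibrate_threshold(screen, set(screen["drug_id"]))
        assert rep["ratio_min"] == pytest.approx(ratios.min())
        assert rep["ratio_max"] == pytest.approx(ratios.max())


class TestSelectSuspected:
    def _screen(self, rows):
        df = pd.DataFrame(rows, columns=["drug_id", "a", "b"])
        df["ratio"] = df["a"] / df["b"]
        return df

    def test_both_criteria_strict(self):
        screen = self._screen([
            ("at_threshold", 201, 2010),      # ratio 0.1 exactly -> not suspected
            ("at_min_users", 300, 2000),      # b = 2000 exactly -> not suspected
            ("clears_both", 300, 2001),
        ])
        out = select_suspected(screen).set_index("drug_id")
        assert not out.loc["at_threshold", "suspected"]
        assert not out.loc["at_min_users", "suspected"]
        assert out.loc["clears_both", "suspected"]

    def test_excluded_ids_never_suspected(self):
        screen = self._screen([("solvent", 500, 3000)])
        out = select_suspected(screen, exclude_ids={"solvent"})
        assert not out["suspected"].any()

    def test_sorted_by_ratio_descending(self):
        screen = self._screen([("lo", 100, 1000), ("hi", 300, 1000), ("mid", 200, 1000)])
        out = select_suspected(screen)
        assert list(out["drug_id"]) == ["hi", "mid", "lo"]
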