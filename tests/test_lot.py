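"""Line-of-therapy engine: runouts, regimen window, advancement rules,
classification, and structural properties."""

import numpy as np
import pandas as pd
import pytest

from oncolot.config import AnalysisConfig
from oncolot.cohort import build_cohort
from oncolot.lot import (ADVANCE_GAP, ADVANCE_NEW_DRUG,
                         ABSORB_MAINTENANCE, CONTINUE, DrugEpisode,
                         LotSegment, assemble_initial_regimen,
                         classify_regimen, derive_all_lots,
                         episode_frame, evaluate_event)

from conftest import make_dataset


def ep(dictionary, name, day, runout=None):
    e = dictionary.by_name(name)
    return DrugEpisode(
        patient_id="p1", drug_code=e.drug_code,
        canonical_id=e.canonical_id, drug_class=e.drug_class,
        maintenance_eligible=e.maintenance_eligible, start_day=day,
        runout_day=day + e.default_runout_days - 1 if runout is None
        else runout)


def seg(regimen, max_runout, start=0):
    return LotSegment(patient_id="p1", lot_number=1, start_day=start,
                      end_day=10 ** 6, regimen=frozenset(regimen),
                      category="", end_reason="", max_runout_day=max_runout)


class TestEpisodes:
    def test_pharmacy_runout_is_fill_plus_supply_minus_one(self):
        ds = make_dataset(
            patients=[{"patient_id": "p1"}],
            enrollment=[{"patient_id": "p1", "start_date": "2020-01-01",
                         "end_date": "2020-12-31"}],
            pharmacy=[{"patient_id": "p1", "fill_date": "2020-05-01",
                       "drug_code": "J9305", "days_supply": 21}])
        frame = episode_frame(ds)
        assert frame.iloc[0]["runout_day"] \
            == frame.iloc[0]["start_day"] + 20

    def test_infusion_runout_uses_default_runout_days(self):
        ds = make_dataset(
            patients=[{"patient_id": "p1"}],
            enrollment=[{"patient_id": "p1", "start_date": "2020-01-01",
                         "end_date": "2020-12-31"}],
            medical=[{"patient_id": "p1", "service_date": "2020-05-01",
                      "drug_code": "J9271"}])
        frame = episode_frame(ds)
        assert frame.iloc[0]["runout_day"] \
            == frame.iloc[0]["start_day"] + 20

    def test_platinum_claims_collapse_to_one_canonical_agent(self,
                                                             dictionary):
        a = ep(dictionary, "carboplatin", 0)
        b = ep(dictionary, "cisplatin", 14)
        assert a.canonical_id == b.canonical_id == "platinum_agent"


class TestRegimenWindow:
    def test_day0_and_day29_join_regimen(self, dictionary):
        eps = [ep(dictionary, "carboplatin", 0),
               ep(dictionary, "pemetrexed", 29)]
        reg = assemble_initial_regimen(eps, 0)
        assert reg == {"platinum_agent", "pemetrexed"}

    def test_day30_is_outside_window(self, dictionary):
        eps = [ep(dictionary, "carboplatin", 0),
               ep(dictionary, "docetaxel", 30)]
        reg = assemble_initial_regimen(eps, 0)
        assert reg == {"platinum_agent"}

    def test_substituted_platinums_are_one_member(self, dictionary):
        eps = [ep(dictionary, "cisplatin", 0),
               ep(dictionary, "carboplatin", 14)]
        assert assemble_initial_regimen(eps, 0) == {"platinum_agent"}


class TestEvaluateEvent:
    def test_reintroduction_of_regimen_drug_continues(self, dictionary):
        current = seg({"pembrolizumab", "platinum_agent", "pemetrexed"},
                      max_runout=41)
        event = ep(dictionary, "pemetrexed", 45)
        assert evaluate_event(current, event, dictionary) == CONTINUE

    def test_new_drug_advances(self, dictionary):
        current = seg({"platinum_agent", "paclitaxel_taxane"},
                      max_runout=55)
        event = ep(dictionary, "docetaxel", 70)
        assert evaluate_event(current, event, dictionary) \
            == ADVANCE_NEW_DRUG

    def test_gap_of_exactly_60_days_advances_even_in_regimen(
            self, dictionary):
        current = seg({"pembrolizumab"}, max_runout=100)
        event = ep(dictionary, "pembrolizumab", 160)
        assert evaluate_event(current, event, dictionary) == ADVANCE_GAP

    def test_gap_of_59_days_does_not_advance(self, dictionary):
        current = seg({"pembrolizumab"}, max_runout=100)
        event = ep(dictionary, "pembrolizumab", 159)
        assert evaluate_event(current, event, dictionary) == CONTINUE

    def test_maintenance_drug_absorbed_on_platinum_backbone(
            self, dictionary):
        current = seg({"platinum_agent", "paclitaxel_taxane"},
                      max_runout=41)
        event = ep(dictionary, "pemetrexed", 50)
        assert evaluate_event(current, event, dictionary) \
            == ABSORB_MAINTENANCE

    def test_maintenance_without_backbone_advances(self, dictionary):
        current = seg({"docetaxel"}, max_runout=41)
        event = ep(dictionary, "pemetrexed", 50)
        assert evaluate_event(current, event, dictionary) \
            == ADVANCE_NEW_DRUG


CLASSIFY_CASES = [
    ({"pembrolizumab", "platinum_agent", "pemetrexed"}, "ICI_PBCT"),
    ({"nivolumab", "ipilimumab"}, "ICI_MONO_DUAL"),
    ({"pembrolizumab"}, "ICI_MONO_DUAL"),
    ({"pembrolizumab", "gemcitabine"}, "ICI_NONPBCT"),
    ({"platinum_agent", "paclitaxel_taxane"}, "PBCT_MONO_COMBO"),
    ({"platinum_agent"}, "PBCT_MONO_COMBO"),
    ({"docetaxel"}, "NONPBCT_MONO"),
    ({"gemcitabine", "vinorelbine"}, "NONPBCT_COMBO"),
    ({"bevacizumab"}, "OTHER"),
    ({"bevacizumab", "pembrolizumab"}, "OTHER"),
    ({"bevacizumab", "platinum_agent", "pemetrexed"}, "PBCT_MONO_COMBO"),
    ({"osimertinib"}, "OTHER"),
]


@pytest.mark.parametrize("regimen,expected", CLASSIFY_CASES)
def test_classify_regimen(dictionary, regimen, expected):
    assert classify_regimen(frozenset(regimen), dictionary) == expected


def _pipeline(medical, enrollment_end="2023-12-31"):
    ds = make_dataset(
        patients=[{"patient_id": "p1"}],
        enrollment=[{"patient_id": "p1", "start_date": "2019-01-01",
                     "end_date": enrollment_end}],
        medical=medical)
    cohort, _ = build_cohort(ds)
    return ds, cohort


def _claims(days_drugs, base="2020-03-20"):
    base_ts = pd.Timestamp(base)
    claims = [
        {"patient_id": "p1", "service_date": "2020-02-01",
         "dx_codes": "C34.90"},
        {"patient_id": "p1", "service_date": "2020-03-01",
         "dx_codes": "C79.51"},
    ]
    for offset, code in days_drugs:
        claims.append({"patient_id": "p1",
                       "service_date":
                       (base_ts + pd.Timedelta(days=offset))
                       .date().isoformat(),
                       "drug_code": code})
    return claims


class TestDeriveLots:
    def test_single_regimen_is_one_segment(self):
        ds, cohort = _pipeline(_claims([(0, "J9045"), (21, "J9045"),
                                        (42, "J9045")]))
        lots = derive_all_lots(ds, cohort)
        assert len(lots) == 1
        assert lots.iloc[0]["end_reason"] in ("STUDY_END",
                                              "ENROLLMENT_END")
        assert lots.iloc[0]["category"] == "PBCT_MONO_COMBO"

    def test_59_day_gap_stays_one_segment(self):
        # runout of day-21 claim is day 41; next claim day 100 -> gap 59
        ds, cohort = _pipeline(_claims([(0, "J9045"), (21, "J9045"),
                                        (100, "J9045")]))
        lots = derive_all_lots(ds, cohort)
        assert len(lots) == 1

    def test_60_day_gap_opens_second_segment(self):
        ds, cohort = _pipeline(_claims([(0, "J9045"), (21, "J9045"),
                                        (101, "J9045")]))
        lots = derive_all_lots(ds, cohort)
        assert list(lots["lot_number"]) == [1, 2]
        assert lots.iloc[0]["end_reason"] == "GAP"
        # first segment ends the day before the next line starts
        assert lots.iloc[0]["end_day"] == lots.iloc[1]["start_day"] - 1

    def test_new_drug_after_window_opens_second_segment(self):
        ds, cohort = _pipeline(_claims([(0, "J9045"), (21, "J9045"),
                                        (42, "J9171")]))
        lots = derive_all_lots(ds, cohort)
        assert list(lots["lot_number"]) == [1, 2]
        assert lots.iloc[0]["end_reason"] == "NEW_DRUG"
        assert lots.iloc[1]["regimen"] == "docetaxel"

    def test_maintenance_extends_line_without_joining_regimen(self):
        ds, cohort = _pipeline(_claims([
            (0, "J9045"), (0, "J9267"), (21, "J9045"),
            (42, "J9305"), (63, "J9305")]))  # pemetrexed maintenance
        lots = derive_all_lots(ds, cohort)
        assert len(lots) == 1
        assert "pemetrexed" not in lots.iloc[0]["regimen"]
        # but the absorbed episodes extend the runout anchor
        assert lots.iloc[0]["max_runout_day"] \
            == lots.iloc[0]["start_day"] + 63 + 20

    def test_substitution_swap_never_changes_segments(self, sim_small):
        """Swapping cisplatin for carboplatin leaves every boundary and
        category unchanged."""
        _, ds, truth = sim_small
        cohort, _ = build_cohort(ds)
        base = derive_all_lots(ds, cohort)
        swapped = ds.medical_claims.copy()
        swapped["drug_code"] = swapped["drug_code"].replace(
            {"J9045": "J9060", "J9060": "J9045"})
        ds2 = type(ds)(ds.patients, ds.enrollment, swapped,
                       ds.pharmacy_claims, ds.dictionary)
        alt = derive_all_lots(ds2, cohort)
        cols = ["patient_id", "lot_number", "start_day", "end_day",
                "category", "end_reason"]
        pd.testing.assert_frame_equal(base[cols], alt[cols])

    def test_idempotent(self, sim_small):
        _, ds, _ = sim_small
        cohort, _ = build_cohort(ds)
        a = derive_all_lots(ds, cohort)
        b = derive_all_lots(ds, cohort)
        pd.testing.assert_frame_equal(a, b)

    def test_segments_partition_episodes(self, sim_small):
        """Every SACT episode on/after the 1L start lies in exactly one
        segment; segments never overlap."""
        _, ds, _ = sim_small
        cohort, _ = build_cohort(ds)
        lots = derive_all_lots(ds, cohort)
        frame = episode_frame(ds)
        elig = cohort[cohort["eligible"]].set_index("patient_id")
        for pid, grp in lots.groupby("patient_id"):
            grp = grp.sort_values("lot_number")
            starts = grp["start_day"].values
            ends = grp["end_day"].values
            assert (starts[1:] > ends[:-1]).all()
            eps = frame[(frame["patient_id"] == pid)
                        & (frame["start_day"] >= starts[0])
                        & (frame["start_day"] <= ends[-1])]
            hits = ((eps["start_day"].values[:, None] >= starts)
                    & (eps["start_day"].values[:, None] <= ends))
            assert (hits.sum(axis=1) == 1).all()

    def test_lot_recovery_matches_ground_truth(self, sim_small):
        _, ds, truth = sim_small
        cohort, _ = build_cohort(ds)
        lots = derive_all_lots(ds, cohort)
        derived = lots.groupby("patient_id")["start_date"].apply(
            lambda s: "|".join(d.strftime("%Y-%m-%d") for d in sorted(s)))
        elig = truth[truth["eligible"]].set_index("patient_id")
        assert (elig["true_lot_starts"]
                == derived.reindex(elig.index)).all()
        cat = lots[lots["lot_number"] == 1].set_index(
            "patient_id")["category"]
        assert (elig["true_category"] == cat.reindex(elig.index)).all()
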