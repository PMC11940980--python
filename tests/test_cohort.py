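"""Eligibility cascade, key-date derivation, baseline lookback."""

import pandas as pd
import pytest

from oncolot.cohort import (FILTERS, baseline_profile, build_cohort,
                            check_enrollment, derive_dx_date,
                            derive_index_date, derive_sm_date)
from oncolot.config import AnalysisConfig
from oncolot.dataset import empty_dataset

from conftest import make_dataset


def _basic(medical, enrollment=None, pharmacy=(), patients=None):
    return make_dataset(
        patients=patients or [{"patient_id": "p1"}],
        enrollment=enrollment or [
            {"patient_id": "p1", "start_date": "2019-01-01",
             "end_date": "2023-12-31"}],
        medical=medical, pharmacy=pharmacy)


class TestKeyDates:
    def test_dx_date_is_earliest_lung_claim(self):
        ds = _basic([
            {"patient_id": "p1", "service_date": "2020-03-01",
             "dx_codes": "C34.10"},
            {"patient_id": "p1", "service_date": "2020-02-01",
             "dx_codes": "C34.90"}])
        assert derive_dx_date(ds)["p1"] == pd.Timestamp("2020-02-01")

    def test_non_lung_dx_yields_no_dx_date(self):
        ds = _basic([{"patient_id": "p1", "service_date": "2020-02-01",
                      "dx_codes": "I10"}])
        assert "p1" not in derive_dx_date(ds)

    def test_lung_code_counts_in_any_position(self):
        ds = _basic([{"patient_id": "p1", "service_date": "2020-02-01",
                      "dx_codes": "I10|E11.9|C34.12"}])
        assert derive_dx_date(ds)["p1"] == pd.Timestamp("2020-02-01")

    def test_sm_on_dx_date_counts(self):
        ds = _basic([{"patient_id": "p1", "service_date": "2020-02-01",
                      "dx_codes": "C34.90|C79.51"}])
        dx = derive_dx_date(ds)
        assert derive_sm_date(ds, dx)["p1"] == pd.Timestamp("2020-02-01")

    def test_pre_dx_metastasis_only_yields_no_sm(self):
        ds = _basic([
            {"patient_id": "p1", "service_date": "2020-02-11",
             "dx_codes": "C34.90"},
            {"patient_id": "p1", "service_date": "2020-02-01",
             "dx_codes": "C78.00"}])
        dx = derive_dx_date(ds)
        assert "p1" not in derive_sm_date(ds, dx)

    def test_sm_is_earliest_qualifying(self):
        ds = _basic([
            {"patient_id": "p1", "service_date": "2020-02-01",
             "dx_codes": "C34.90"},
            {"patient_id": "p1", "service_date": "2020-03-01",
             "dx_codes": "C79.31"},
            {"patient_id": "p1", "service_date": "2020-04-01",
             "dx_codes": "C78.7"}])
        dx = derive_dx_date(ds)
        assert derive_sm_date(ds, dx)["p1"] == pd.Timestamp("2020-03-01")

    def test_index_is_first_sact_on_or_after_sm(self):
        ds = _basic([
            {"patient_id": "p1", "service_date": "2020-02-01",
             "dx_codes": "C34.90|C79.51"},
            {"patient_id": "p1", "service_date": "2020-02-21",
             "drug_code": "J9045"}])
        dx = derive_dx_date(ds)
        sm = derive_sm_date(ds, dx)
        assert derive_index_date(ds, sm)["p1"] == pd.Timestamp(
            "2020-02-21")

    def test_pre_sm_sact_does_not_set_index(self):
        ds = _basic([
            {"patient_id": "p1", "service_date": "2020-02-01",
             "dx_codes": "C34.90"},
            {"patient_id": "p1", "service_date": "2020-02-10",
             "drug_code": "J9045"},
            {"patient_id": "p1", "service_date": "2020-03-01",
             "dx_codes": "C79.51"}])
        dx = derive_dx_date(ds)
        sm = derive_sm_date(ds, dx)
        assert "p1" not in derive_index_date(ds, sm)

    def test_pharmacy_fill_can_set_index(self):
        ds = _basic(
            medical=[{"patient_id": "p1", "service_date": "2020-02-01",
                      "dx_codes": "C34.90|C79.51"}],
            pharmacy=[{"patient_id": "p1", "fill_date": "2020-02-15",
                       "drug_code": "J9305", "days_supply": 21}])
        dx = derive_dx_date(ds)
        sm = derive_sm_date(ds, dx)
        assert derive_index_date(ds, sm)["p1"] == pd.Timestamp(
            "2020-02-15")


class TestEnrollment:
    DX = pd.Timestamp("2020-06-01")
    IDX = pd.Timestamp("2020-08-01")

    def _check(self, spans):
        ds = _basic([], enrollment=spans)
        return check_enrollment(ds, "p1", self.DX, self.IDX)

    def test_full_coverage_passes(self):
        assert self._check([{"patient_id": "p1",
                             "start_date": "2019-01-01",
                             "end_date": "2021-12-31"}])

    def test_one_day_hole_fails(self):
        hole = self.DX - pd.Timedelta(days=90)
        assert not self._check([
            {"patient_id": "p1", "start_date": "2019-01-01",
             "end_date": (hole - pd.Timedelta(days=1)).date().isoformat()},
            {"patient_id": "p1",
             "start_date": (hole + pd.Timedelta(days=1)).date().isoformat(),
             "end_date": "2021-12-31"}])

    def test_span_ending_exactly_30_days_after_index_passes(self):
        end = (self.IDX + pd.Timedelta(days=30)).date().isoformat()
        assert self._check([{"patient_id": "p1",
                             "start_date": "2019-01-01",
                             "end_date": end}])

    def test_span_ending_29_days_after_index_fails(self):
        end = (self.IDX + pd.Timedelta(days=29)).date().isoformat()
        assert not self._check([{"patient_id": "p1",
                                 "start_date": "2019-01-01",
                                 "end_date": end}])

    def test_medical_only_coverage_fails(self):
        ds = _basic([], enrollment=[
            {"patient_id": "p1", "start_date": "2019-01-01",
             "end_date": "2021-12-31", "pharmacy": False}])
        assert not check_enrollment(ds, "p1", self.DX, self.IDX)


def _eligible_claims(pid="p1"):
    """Claim stream of a straightforwardly eligible patient."""
    return [
        {"patient_id": pid, "service_date": "2020-02-01",
         "dx_codes": "C34.90"},
        {"patient_id": pid, "service_date": "2020-03-01",
         "dx_codes": "C79.51"},
        {"patient_id": pid, "service_date": "2020-03-20",
         "drug_code": "J9045"},
        {"patient_id": pid, "service_date": "2020-03-20",
         "drug_code": "J9271"},
    ]


class TestExclusions:
    def _cohort(self, extra_med=(), extra_pha=()):
        ds = _basic(_eligible_claims() + list(extra_med),
                    pharmacy=list(extra_pha))
        rows, _ = build_cohort(ds)
        return rows.iloc[0]

    def test_clean_patient_is_eligible(self):
        row = self._cohort()
        assert row["eligible"]
        assert row["failed_filter"] == ""

    def test_targeted_claim_after_index_excludes(self):
        row = self._cohort(extra_pha=[
            {"patient_id": "p1", "fill_date": "2020-06-01",
             "drug_code": "00310155030"}])  # osimertinib
        assert not row["eligible"]
        assert row["failed_filter"] == "no_targeted_treatment"

    def test_vegf_does_not_trigger_targeted_exclusion(self):
        row = self._cohort(extra_med=[
            {"patient_id": "p1", "service_date": "2020-06-01",
             "drug_code": "J9035"}])  # bevacizumab
        assert row["eligible"]

    def test_sclc_agent_before_index_excludes(self):
        row = self._cohort(extra_med=[
            {"patient_id": "p1", "service_date": "2020-02-18",
             "drug_code": "J9351"}])  # topotecan, after dx, before sm
        assert not row["eligible"]
        assert row["failed_filter"] == "no_sclc_treatment_before_index"

    def test_pre_dx_metastasis_excludes(self):
        row = self._cohort(extra_med=[
            {"patient_id": "p1", "service_date": "2019-12-01",
             "dx_codes": "C79.9"}])
        assert not row["eligible"]
        assert row["failed_filter"] == "no_pre_dx_sm_or_sact"

    def test_index_before_floor_excludes(self):
        claims = [dict(c) for c in _eligible_claims()]
        for c in claims:
            c["service_date"] = c["service_date"].replace("2020", "2019")
        ds = _basic(claims)
        rows, _ = build_cohort(ds)
        assert rows.iloc[0]["failed_filter"] == "index_on_or_after_2020"

    def test_minor_excluded_on_age(self):
        ds = _basic(_eligible_claims(),
                    patients=[{"patient_id": "p1", "birth_year": 2010}])
        rows, _ = build_cohort(ds)
        assert rows.iloc[0]["failed_filter"] == "age_18_plus"


class TestAttrition:
    def test_counts_nonincreasing(self, sim_small):
        _, ds, _ = sim_small
        _, attrition = build_cohort(ds)
        counts = [n for _, n in attrition.rows]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_injected_failures_recovered_exactly(self, sim_small):
        """Every deliberately ineligible patient fails exactly the
        intended criterion (diagonal confusion matrix)."""
        _, ds, truth = sim_small
        rows, _ = build_cohort(ds)
        merged = rows.merge(truth, on="patient_id")
        assert (merged["eligible_x"] == merged["eligible_y"]).all()
        assert (merged["failed_filter_x"]
                == merged["failed_filter_y"]).all()

    def test_empty_dataset_gives_zero_counts(self):
        rows, attrition = build_cohort(empty_dataset())
        assert len(rows) == 0
        assert all(n == 0 for _, n in attrition.rows)
        assert [c for c, _ in attrition.rows] == FILTERS


class TestBaseline:
    def _profile(self, extra_med):
        ds = _basic(_eligible_claims() + list(extra_med))
        return baseline_profile(ds, "p1", pd.Timestamp("2020-03-20"))

    def test_comorbidity_inside_window_flagged(self):
        prof = self._profile([{"patient_id": "p1",
                               "service_date": "2020-02-19",
                               "dx_codes": "I10"}])
        assert prof["hypertension"]

    def test_claim_on_index_date_not_counted(self):
        prof = self._profile([{"patient_id": "p1",
                               "service_date": "2020-03-20",
                               "dx_codes": "I10"}])
        assert not prof["hypertension"]

    def test_claim_before_lookback_not_counted(self):
        prof = self._profile([{"patient_id": "p1",
                               "service_date": "2019-09-01",
                               "dx_codes": "I10"}])
        assert not prof["hypertension"]

    def test_unit_weight_cci_sums_flags(self):
        ds = _basic(_eligible_claims() + [
            {"patient_id": "p1", "service_date": "2020-02-19",
             "dx_codes": "E11.9|J44.9"}])
        config = AnalysisConfig(charlson_weights={"diabetes": 1.0,
                                                  "copd": 1.0})
        prof = baseline_profile(ds, "p1", pd.Timestamp("2020-03-20"),
                                config)
        assert prof["nci_cci"] == pytest.approx(2.0)

    def test_smoking_from_nicotine_dependence_codes(self):
        prof = self._profile([{"patient_id": "p1",
                               "service_date": "2020-02-19",
                               "dx_codes": "F17.210"}])
        assert prof["smoking_history"]
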