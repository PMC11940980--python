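import numpy as np
import pandas as pd
import pytest

from oncolot.config import AnalysisConfig
from oncolot.dataset import ClaimsDataset
from oncolot.dictionary import DrugDictionary
from oncolot.simulate import CalibrationConfig, generate

PATIENT_DEFAULTS = {"birth_year": 1950, "sex": "M", "region": "South",
                    "payer": "MedicareAdvantage", "death_date": None}
MED_DEFAULTS = {"setting": "OUTPATIENT", "dx_codes": "", "drug_code": "",
                "paid_amount": 0.0}


def make_dataset(patients, enrollment, medical=(), pharmacy=(),
                 dictionary=None) -> ClaimsDataset:
    """Build a small in-memory dataset from lists of dicts, filling
    defaults; dates may be ISO strings."""
    pat_rows = []
    for p in patients:
        row = {**PATIENT_DEFAULTS, **p}
        pat_rows.append(row)
    pat = pd.DataFrame(pat_rows)
    pat["death_date"] = pd.to_datetime(pat["death_date"])

    enr = pd.DataFrame([{"medical": True, "pharmacy": True, **e}
                        for e in enrollment])
    for c in ("start_date", "end_date"):
        enr[c] = pd.to_datetime(enr[c])

    med_rows = []
    for i, m in enumerate(medical):
        row = {"claim_id": f"M{i:04d}", **MED_DEFAULTS, **m}
        med_rows.append(row)
    med = pd.DataFrame(med_rows, columns=[
        "claim_id", "patient_id", "service_date", "setting", "dx_codes",
        "drug_code", "paid_amount"])
    med["service_date"] = pd.to_datetime(med["service_date"])
    med["dx_codes"] = med["dx_codes"].fillna("").astype(str)
    med["drug_code"] = med["drug_code"].fillna("").astype(str)
    med["paid_amount"] = med["paid_amount"].astype(float)
    med["service_year"] = med["service_date"].dt.year.fillna(0).astype(int)

    pha_rows = []
    for i, p in enumerate(pharmacy):
        row = {"claim_id": f"R{i:04d}", "days_supply": 30,
               "paid_amount": 0.0, **p}
        pha_rows.append(row)
    pha = pd.DataFrame(pha_rows, columns=[
        "claim_id", "patient_id", "fill_date", "drug_code", "days_supply",
        "paid_amount"])
    pha["fill_date"] = pd.to_datetime(pha["fill_date"])
    pha["days_supply"] = pha["days_supply"].fillna(30).astype(int)
    pha["paid_amount"] = pha["paid_amount"].astype(float)
    pha["drug_code"] = pha["drug_code"].fillna("").astype(str)

    return ClaimsDataset(pat, enr, med, pha,
                         dictionary or DrugDictionary.default())


@pytest.fixture(scope="session")
def dictionary() -> DrugDictionary:
    return DrugDictionary.default()


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def sim_small():
    """A small generated dataset + truth shared across tests."""
    calib = CalibrationConfig(n_patients=400, seed=11)
    ds, truth = generate(calib)
    return calib, ds, truth


def code_of(dictionary: DrugDictionary, name: str) -> str:
    return dictionary.by_name(name).drug_code
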