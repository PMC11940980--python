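"""Derive lines of therapy for one hand-built patient.

The patient starts carboplatin + pemetrexed + pembrolizumab, switches
carboplatin for cisplatin mid-course (a substitution, not a new drug),
continues pemetrexed maintenance, and later starts docetaxel — a new
non-regimen drug that opens a second line.
"""

import pandas as pd

from oncolot import build_cohort, derive_all_lots
from oncolot.dataset import ClaimsDataset
from oncolot.dictionary import DrugDictionary


def claim(i, date, dx="", drug=""):
    return {"claim_id": f"M{i}", "patient_id": "p1", "service_date": date,
            "setting": "OUTPATIENT", "dx_codes": dx, "drug_code": drug,
            "paid_amount": 0.0}


rows = [
    claim(0, "2020-02-01", dx="C34.90"),          # lung cancer dx
    claim(1, "2020-03-01", dx="C79.51"),          # bone metastasis
    claim(2, "2020-03-20", drug="J9045"),         # carboplatin  (1L start)
    claim(3, "2020-03-20", drug="J9305"),         # pemetrexed
    claim(4, "2020-03-20", drug="J9271"),         # pembrolizumab
    claim(5, "2020-04-10", drug="J9060"),         # cisplatin (substitution)
    claim(6, "2020-05-01", drug="J9305"),         # pemetrexed maintenance
    claim(7, "2020-07-01", drug="J9171"),         # docetaxel -> 2L
]
med = pd.DataFrame(rows)
med["service_date"] = pd.to_datetime(med["service_date"])
med["service_year"] = med["service_date"].dt.year

patients = pd.DataFrame([{"patient_id": "p1", "birth_year": 1950,
                          "sex": "F", "region": "South",
                          "payer": "MedicareAdvantage",
                          "death_date": pd.NaT}])
enroll = pd.DataFrame([{"patient_id": "p1",
                        "start_date": pd.Timestamp("2019-01-01"),
                        "end_date": pd.Timestamp("2023-12-31"),
                        "medical": True, "pharmacy": True}])
pharm = pd.DataFrame(columns=["claim_id", "patient_id", "fill_date",
                              "drug_code", "days_supply", "paid_amount"])
pharm["fill_date"] = pd.to_datetime(pharm["fill_date"])

ds = ClaimsDataset(patients, enroll, med, pharm,
                   DrugDictionary.default())
cohort, _ = build_cohort(ds)
lots = derive_all_lots(ds, cohort)

cols = ["lot_number", "start_date", "end_date", "regimen", "category",
        "end_reason"]
print(lots[cols].to_string(index=False))
print()
print("Line 1 is ICI + platinum-based chemotherapy: the cisplatin claim "
      "collapses into the same\nsubstitution group as carboplatin and "
      "pemetrexed maintenance extends the line, so only\nthe docetaxel "
      "claim (a new non-regimen drug) advances the line of therapy.")
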