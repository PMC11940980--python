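"""Per-patient-per-month utilization and cost summaries.

Everything is attributed to the SACT period (the costing window derived
in :mod:`oncolot.outcomes`); claims outside it contribute nothing.
Utilization is counted by setting: outpatient and emergency-department
visits are distinct service dates, inpatient admissions are runs of
adjacent inpatient dates collapsed into stays, pharmacy use is fill
counts.  Costs are paid amounts restated in reference-year dollars with
the medical component of the CPI, summed per patient per setting;
oncology drug administrations are outpatient claims, so drug costs ride
with the outpatient setting.

Each quantity is divided by the patient's observed months (period days /
month length) first, then averaged across patients — the per-patient
per-month (PPPM) convention.  A claim is NSCLC-related if any diagnosis
position carries a lung-cancer code or the claim is for a lung-cancer
medication (any SACT class, plus a configurable supportive list).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .cohort import dx_flag
from .dataset import ClaimsDataset, to_days
from .dictionary import SACT_CLASSES

SETTINGS = ("outpatient", "inpatient", "ed", "pharmacy")


def adjust_cost(paid_amount: float, service_year: int,
                config: AnalysisConfig) -> float:
    """Restate a paid amount in reference-year dollars via the CPI table."""
    for year in (service_year, config.reference_year):
        if year not in config.cpi_table:
            raise ValueError(f"cpi_table has no entry for year {year}")
    return paid_amount * config.cpi_table[config.reference_year] \
        / config.cpi_table[service_year]


def _adjust_vector(paid: np.ndarray, years: np.ndarray,
                   config: AnalysisConfig) -> np.ndarray:
    missing = sorted(set(years) - set(config.cpi_table))
    if missing:
        raise ValueError(f"cpi_table has no entry for year(s) {missing}")
    ref = config.cpi_table[config.reference_year]
    factors = np.array([ref / config.cpi_table[y] for y in years])
    return paid * factors


def _nsclc_drug_names(ds: ClaimsDataset,
                      config: AnalysisConfig) -> set[str]:
    names = {e.generic_name for e in ds.dictionary.entries()
             if e.drug_class in SACT_CLASSES}
    return names | set(config.nsclc_supportive_drugs)


def flag_nsclc_related(claim: pd.Series, ds: ClaimsDataset,
                       config: AnalysisConfig | None = None) -> bool:
    """True iff any dx position is lung-cancer coded or the drug is a
    lung-cancer medication."""
    config = config or AnalysisConfig()
    dx = str(claim.get("dx_codes", "") or "")
    if dx and dx_flag(pd.DataFrame({"dx_codes": [dx]}),
                      config.lung_cancer_prefixes).iloc[0]:
        return True
    code = str(claim.get("drug_code", "") or "")
    if not code or code not in ds.dictionary:
        return False
    entry = ds.dictionary.lookup(code)
    return entry.drug_class in SACT_CLASSES \
        or entry.generic_name in config.nsclc_supportive_drugs


def compute_pppm(value, period_days, config: AnalysisConfig | None = None):
    """A count or cost divided by the patient's observed months."""
    config = config or AnalysisConfig()
    period_days = np.asarray(period_days, dtype=float)
    if np.any(period_days < 1):
        raise ValueError("SACT period must be at least one day")
    return np.asarray(value, dtype=float) \
        / (period_days / config.month_length_days)


def attribute_claims(ds: ClaimsDataset, periods: pd.DataFrame,
                     config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-claim attribution for patients with a SACT period.

    Returns one row per claim with setting (pharmacy claims get setting
    PHARMACY), day, in_sact_period, nsclc_related, adjusted_cost.
    """
    config = config or AnalysisConfig()
    pmap = periods.set_index("patient_id")
    names = _nsclc_drug_names(ds, config)
    code_name = {e.drug_code: e.generic_name
                 for e in ds.dictionary.entries()}

    med = ds.medical_claims[
        ds.medical_claims["patient_id"].isin(pmap.index)].copy()
    med_related = dx_flag(med, config.lung_cancer_prefixes) \
        | med["drug_code"].map(code_name).isin(names)
    med_out = pd.DataFrame({
        "claim_id": med["claim_id"],
        "patient_id": med["patient_id"],
        "setting": med["setting"],
        "day": to_days(med["service_date"]),
        "nsclc_related": med_related.values,
        "adjusted_cost": _adjust_vector(
            med["paid_amount"].values,
            med["service_year"].values, config),
    })

    pha = ds.pharmacy_claims[
        ds.pharmacy_claims["patient_id"].isin(pmap.index)].copy()
    pha_out = pd.DataFrame({
        "claim_id": pha["claim_id"],
        "patient_id": pha["patient_id"],
        "setting": "PHARMACY",
        "day": to_days(pha["fill_date"]),
        "nsclc_related": pha["drug_code"].map(code_name).isin(names).values,
        "adjusted_cost": _adjust_vector(
            pha["paid_amount"].values,
            pha["fill_date"].dt.year.values, config),
    })

    out = pd.concat([med_out, pha_out], ignore_index=True)
    start = out["patient_id"].map(pmap["start_day"])
    end = out["patient_id"].map(pmap["end_day"])
    out["in_sact_period"] = (out["day"] >= start) & (out["day"] <= end)
    return out


def _stay_counts(claims: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(all-cause stays, NSCLC-related stays) per patient from in-period
    inpatient claims; adjacent dates collapse into one stay."""
    inp = claims[(claims["setting"] == "INPATIENT")
                 & claims["in_sact_period"]]
    if not len(inp):
        empty = pd.Series(dtype=int)
        return empty, empty
    days = inp[["patient_id", "day"]].drop_duplicates().sort_values(
        ["patient_id", "day"])
    new_stay = (days["patient_id"] != days["patient_id"].shift()) \
        | (days["day"] > days["day"].shift() + 1)
    days = days.assign(stay_id=np.cumsum(new_stay.values))
    stays = days.groupby("patient_id")["stay_id"].nunique()
    claim_stay = inp.merge(days, on=["patient_id", "day"])
    rel = claim_stay.groupby(["patient_id", "stay_id"])["nsclc_related"] \
        .any().reset_index()
    rel_stays = rel[rel["nsclc_related"]].groupby("patient_id")["stay_id"] \
        .nunique()
    return stays, rel_stays


def patient_pppm_table(ds: ClaimsDataset, periods: pd.DataFrame,
                       config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-patient PPPM utilization and cost, all-cause and NSCLC-related.

    One row per patient with a SACT period; utilization columns
    visits_outpatient / adm_inpatient / visits_ed / fills_pharmacy and
    cost_<setting> plus cost_total, each with an ``nsclc_`` twin.
    """
    config = config or AnalysisConfig()
    claims = attribute_claims(ds, periods, config)
    inper = claims[claims["in_sact_period"]]

    base = periods.set_index("patient_id").copy()
    months = (base["end_day"] - base["start_day"] + 1) \
        / config.month_length_days
    out = pd.DataFrame(index=base.index)
    out["category"] = base["category"]
    out["period_days"] = base["end_day"] - base["start_day"] + 1

    def per_month(series: pd.Series) -> pd.Series:
        return (series.reindex(base.index).fillna(0.0) / months)

    def date_counts(setting: str, related_only: bool) -> pd.Series:
        sub = inper[inper["setting"] == setting]
        if related_only:
            sub = sub[sub["nsclc_related"]]
        return sub.groupby("patient_id")["day"].nunique()

    out["visits_outpatient"] = per_month(date_counts("OUTPATIENT", False))
    out["nsclc_visits_outpatient"] = per_month(date_counts("OUTPATIENT",
                                                           True))
    out["visits_ed"] = per_month(date_counts("ED", False))
    out["nsclc_visits_ed"] = per_month(date_counts("ED", True))
    stays, rel_stays = _stay_counts(claims)
    out["adm_inpatient"] = per_month(stays)
    out["nsclc_adm_inpatient"] = per_month(rel_stays)
    fills = inper[inper["setting"] == "PHARMACY"]
    out["fills_pharmacy"] = per_month(
        fills.groupby("patient_id")["claim_id"].count())
    out["nsclc_fills_pharmacy"] = per_month(
        fills[fills["nsclc_related"]].groupby("patient_id")["claim_id"]
        .count())

    for setting in SETTINGS:
        sub = inper[inper["setting"] == setting.upper()]
        out[f"cost_{setting}"] = per_month(
            sub.groupby("patient_id")["adjusted_cost"].sum())
        out[f"nsclc_cost_{setting}"] = per_month(
            sub[sub["nsclc_related"]]
            .groupby("patient_id")["adjusted_cost"].sum())
    out["cost_total"] = sum(out[f"cost_{s}"] for s in SETTINGS)
    out["nsclc_cost_total"] = sum(out[f"nsclc_cost_{s}"] for s in SETTINGS)
    return out.reset_index()


_UTIL_COLS = {
    "outpatient": "visits_outpatient",
    "inpatient": "adm_inpatient",
    "ed": "visits_ed",
    "pharmacy": "fills_pharmacy",
}


def summarize(pppm: pd.DataFrame,
              config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Mean/SD/median/IQR of per-patient PPPM values.

    One row per (category incl. pooled 'ALL') x scope (ALL_CAUSE /
    NSCLC_RELATED) x setting (incl. TOTAL for cost) x metric.
    """
    rows = []

    def stats(values: pd.Series) -> dict:
        v = values.astype(float)
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        q1, q3 = (float(v.quantile(0.25)), float(v.quantile(0.75))) \
            if len(v) else (float("nan"),) * 2
        return {"n": int(len(v)), "mean_pppm": float(v.mean()),
                "sd_pppm": sd, "median_pppm": float(v.median()),
                "iqr_low_pppm": q1, "iqr_high_pppm": q3}

    groups = [("ALL", pppm)] + [(str(c), g) for c, g in
                                pppm.groupby("category")]
    for cat, grp in groups:
        for scope, prefix in (("ALL_CAUSE", ""), ("NSCLC_RELATED",
                                                  "nsclc_")):
            for setting, col in _UTIL_COLS.items():
                rows.append({"category": cat, "scope": scope,
                             "setting": setting.upper(),
                             "metric": "utilization",
                             **stats(grp[f"{prefix}{col}"])})
            for setting in (*SETTINGS, "total"):
                rows.append({"category": cat, "scope": scope,
                             "setting": setting.upper(), "metric": "cost",
                             **stats(grp[f"{prefix}cost_{setting}"])})
    return pd.DataFrame(rows)
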