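"""Eligibility cascade, key dates, and baseline characteristics.

The cohort is selected by an ordered cascade of criteria: a lung-cancer
diagnosis (earliest C34-coded claim = Dx date), a metastasis diagnosis on
or after the Dx date (SM date), a first systemic anticancer therapy on or
after the SM date (the index date), an index on or after the configured
floor, continuous medical+pharmacy enrollment from 180 days before Dx to
30 days after index, no SCLC-predominant agent before index, no targeted
therapy anywhere in the study period, no metastasis or SACT in the 180
days before Dx, age >= 18 at index, and a first-line regimen containing
at least one NSCLC-appropriate agent.  Each patient is labelled with the
FIRST criterion failed, so the attrition table decrements exactly once
per patient.

Baseline comorbidity flags, metastasis sites, smoking history and the
NCI-adapted Charlson index are derived from claims in the 180 days up to
but excluding the index date.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, normalize_dx
from .dataset import ClaimsDataset, merge_intervals, to_days
from .dictionary import SACT_CLASSES

#: cascade order; labels mirror the selection-table rows
FILTERS = [
    "lung_cancer_dx",
    "secondary_malignancy",
    "sact_after_sm",
    "index_on_or_after_2020",
    "continuous_enrollment",
    "no_sclc_treatment_before_index",
    "no_targeted_treatment",
    "no_pre_dx_sm_or_sact",
    "age_18_plus",
    "nsclc_sact_1l",
]

FILTER_LABELS = {
    "lung_cancer_dx": "Diagnosis of lung cancer (Dx date)",
    "secondary_malignancy":
        "Diagnosis of secondary malignancy on or after Dx date",
    "sact_after_sm":
        "SACT for NSCLC on or after diagnosis of secondary malignancy",
    "index_on_or_after_2020":
        ">=1 LOT initiated on or after 1 January 2020 (index date)",
    "continuous_enrollment":
        "Continuously enrolled for >=180 days before diagnosis to "
        ">=30 days after index date",
    "no_sclc_treatment_before_index":
        "No medications typically administered for SCLC before the "
        "index date",
    "no_targeted_treatment":
        "No claims for targeted treatment during the study period",
    "no_pre_dx_sm_or_sact":
        "No diagnosis of secondary malignancy or use of SACT within "
        "180 days prior to Dx date",
    "age_18_plus": "Age >= 18 years on the index date",
    "nsclc_sact_1l": "1L SACT for NSCLC",
}

#: drug classes that make a first-line regimen NSCLC-appropriate
NSCLC_SACT_CLASSES = frozenset({"ICI", "PLATINUM", "NONPLAT_CHEMO", "VEGF"})


def _prefix_pattern(prefixes) -> re.Pattern:
    alts = "|".join(re.escape(normalize_dx(p)) for p in prefixes)
    return re.compile(r"(?:^|\|)(?:%s)" % alts)


def _norm_dx_col(df: pd.DataFrame) -> pd.Series:
    return (df["dx_codes"].str.upper()
            .str.replace(".", "", regex=False))


def dx_flag(df: pd.DataFrame, prefixes) -> pd.Series:
    """True where any diagnosis code (any position) matches a prefix."""
    if not len(df):
        return pd.Series(False, index=df.index)
    return _norm_dx_col(df).str.contains(_prefix_pattern(prefixes))


def _class_map(ds: ClaimsDataset) -> dict[str, str]:
    return {e.drug_code: e.drug_class for e in ds.dictionary.entries()}


def sact_claims(ds: ClaimsDataset) -> pd.DataFrame:
    """All SACT drug claims (medical + pharmacy) as patient/date/class."""
    cmap = _class_map(ds)
    med = ds.medical_claims[ds.medical_claims["drug_code"] != ""]
    med_cls = med["drug_code"].map(cmap)
    med = pd.DataFrame({"patient_id": med["patient_id"],
                        "date": med["service_date"],
                        "drug_code": med["drug_code"],
                        "drug_class": med_cls})
    pha = ds.pharmacy_claims
    pha = pd.DataFrame({"patient_id": pha["patient_id"],
                        "date": pha["fill_date"],
                        "drug_code": pha["drug_code"],
                        "drug_class": pha["drug_code"].map(cmap)})
    allc = pd.concat([med, pha], ignore_index=True)
    return allc[allc["drug_class"].isin(SACT_CLASSES)].reset_index(drop=True)


# -- key dates ----------------------------------------------------------


def derive_dx_date(ds: ClaimsDataset,
                   config: AnalysisConfig | None = None) -> pd.Series:
    """Earliest lung-cancer-coded claim date within the study window."""
    config = config or AnalysisConfig()
    med = ds.medical_claims
    mask = dx_flag(med, config.lung_cancer_prefixes)
    mask &= med["service_date"].between(pd.Timestamp(config.study_start),
                                        pd.Timestamp(config.study_end))
    hits = med.loc[mask, ["patient_id", "service_date"]]
    return hits.groupby("patient_id")["service_date"].min()


def derive_sm_date(ds: ClaimsDataset, dx_dates: pd.Series,
                   config: AnalysisConfig | None = None) -> pd.Series:
    """Earliest metastasis-coded claim on or after the Dx date."""
    config = config or AnalysisConfig()
    med = ds.medical_claims
    mask = dx_flag(med, config.metastasis_prefixes)
    hits = med.loc[mask, ["patient_id", "service_date"]].copy()
    hits["dx"] = hits["patient_id"].map(dx_dates)
    hits = hits[hits["dx"].notna() & (hits["service_date"] >= hits["dx"])]
    return hits.groupby("patient_id")["service_date"].min()


def derive_index_date(ds: ClaimsDataset, sm_dates: pd.Series,
                      config: AnalysisConfig | None = None) -> pd.Series:
    """Earliest SACT claim (service or fill) on or after the SM date."""
    sact = sact_claims(ds)
    sact = sact.copy()
    sact["sm"] = sact["patient_id"].map(sm_dates)
    sact = sact[sact["sm"].notna() & (sact["date"] >= sact["sm"])]
    return sact.groupby("patient_id")["date"].min()


# -- enrollment ---------------------------------------------------------


def _benefit_spans(ds: ClaimsDataset, benefit: str,
                   tolerance: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    enr = ds.enrollment[ds.enrollment[benefit]]
    out = {}
    for pid, grp in enr.groupby("patient_id", sort=False):
        out[pid] = merge_intervals(to_days(grp["start_date"]),
                                   to_days(grp["end_date"]), tolerance)
    return out


def _covers(spans: tuple[np.ndarray, np.ndarray] | None,
            w0: int, w1: int) -> bool:
    if spans is None:
        return False
    s, e = spans
    return bool(np.any((s <= w0) & (e >= w1)))


def check_enrollment(ds: ClaimsDataset, patient_id: str,
                     dx_date: pd.Timestamp, index_date: pd.Timestamp,
                     config: AnalysisConfig | None = None) -> bool:
    """True iff medical and pharmacy benefits each cover every day of
    [dx - lookback, index + post-index requirement] (inclusive ends)."""
    config = config or AnalysisConfig()
    w0 = int(to_days(pd.Series([dx_date]))[0]) - config.pre_dx_lookback_days
    w1 = int(to_days(pd.Series([index_date]))[0]) \
        + config.post_index_enroll_days
    tol = config.enrollment_gap_tolerance_days
    enr = ds.enrollment[ds.enrollment["patient_id"] == patient_id]
    for benefit in ("medical", "pharmacy"):
        grp = enr[enr[benefit]]
        spans = merge_intervals(to_days(grp["start_date"]),
                                to_days(grp["end_date"]), tol)
        if not _covers(spans, w0, w1):
            return False
    return True


# -- cascade ------------------------------------------------------------


@dataclass
class AttritionTable:
    """Ordered (criterion, patients remaining) rows of the cascade."""

    rows: list[tuple[str, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"criterion": c, "label": FILTER_LABELS[c], "remaining": n}
             for c, n in self.rows])


def build_cohort(ds: ClaimsDataset, config: AnalysisConfig | None = None,
                 ) -> tuple[pd.DataFrame, AttritionTable]:
    """Apply the full cascade; returns cohort rows and the attrition table.

    The cohort frame has one row per patient with a lung-cancer
    diagnosis: patient_id, dx_date, sm_date, index_date, index_age,
    eligible, failed_filter ('' when eligible).
    """
    config = config or AnalysisConfig()
    dx = derive_dx_date(ds, config)
    sm = derive_sm_date(ds, dx, config)
    index = derive_index_date(ds, sm, config)

    if not len(dx):
        rows = pd.DataFrame(columns=["patient_id", "dx_date", "sm_date",
                                     "index_date", "index_age",
                                     "eligible", "failed_filter"])
        zeros = [("lung_cancer_dx", 0)] + [(f, 0) for f in FILTERS[1:]]
        return rows, AttritionTable(zeros)

    rows = pd.DataFrame({"patient_id": dx.index, "dx_date": dx.values})
    rows["sm_date"] = rows["patient_id"].map(sm)
    rows["index_date"] = rows["patient_id"].map(index)
    pat = ds.patients.set_index("patient_id")
    rows["birth_year"] = rows["patient_id"].map(pat["birth_year"])
    rows["index_age"] = rows["index_date"].dt.year - rows["birth_year"]

    sact = sact_claims(ds)
    sact["index"] = sact["patient_id"].map(index)
    sact["dx"] = sact["patient_id"].map(dx)

    # SCLC-predominant agent strictly before index
    sclc = sact[(sact["drug_class"] == "SCLC_TYPICAL")
                & sact["index"].notna()
                & (sact["date"] < sact["index"])]
    sclc_flag = rows["patient_id"].isin(set(sclc["patient_id"]))

    # targeted therapy anywhere in the study period
    targ = sact[(sact["drug_class"] == "TARGETED")
                & sact["date"].between(pd.Timestamp(config.study_start),
                                       pd.Timestamp(config.study_end))]
    targ_flag = rows["patient_id"].isin(set(targ["patient_id"]))

    # metastasis dx or SACT within the pre-Dx lookback
    look = pd.Timedelta(days=config.pre_dx_lookback_days)
    med = ds.medical_claims
    met_mask = dx_flag(med, config.metastasis_prefixes)
    met = med.loc[met_mask, ["patient_id", "service_date"]].copy()
    met["dx"] = met["patient_id"].map(dx)
    pre_met = met[met["dx"].notna()
                  & (met["service_date"] >= met["dx"] - look)
                  & (met["service_date"] < met["dx"])]
    pre_sact = sact[sact["dx"].notna()
                    & (sact["date"] >= sact["dx"] - look)
                    & (sact["date"] < sact["dx"])]
    predx_flag = rows["patient_id"].isin(
        set(pre_met["patient_id"]) | set(pre_sact["patient_id"]))

    # first-line regimen contains an NSCLC-appropriate agent
    win = pd.Timedelta(days=config.regimen_window_days - 1)
    reg = sact[sact["index"].notna()
               & (sact["date"] >= sact["index"])
               & (sact["date"] <= sact["index"] + win)
               & sact["drug_class"].isin(NSCLC_SACT_CLASSES)]
    nsclc_flag = rows["patient_id"].isin(set(reg["patient_id"]))

    med_spans = _benefit_spans(ds, "medical",
                               config.enrollment_gap_tolerance_days)
    pha_spans = _benefit_spans(ds, "pharmacy",
                               config.enrollment_gap_tolerance_days)
    dx_days = to_days(rows["dx_date"])
    idx_days = to_days(rows["index_date"])
    has_index = rows["index_date"].notna().values
    enroll_ok = np.zeros(len(rows), dtype=bool)
    for i, pid in enumerate(rows["patient_id"].values):
        if not has_index[i]:
            continue
        w0 = dx_days[i] - config.pre_dx_lookback_days
        w1 = idx_days[i] + config.post_index_enroll_days
        enroll_ok[i] = (_covers(med_spans.get(pid), w0, w1)
                        and _covers(pha_spans.get(pid), w0, w1))

    floor = pd.Timestamp(config.index_floor)
    checks = [
        ("secondary_malignancy", rows["sm_date"].notna().values),
        ("sact_after_sm", rows["index_date"].notna().values),
        ("index_on_or_after_2020",
         (rows["index_date"] >= floor).fillna(False).values),
        ("continuous_enrollment", enroll_ok),
        ("no_sclc_treatment_before_index", ~sclc_flag.values),
        ("no_targeted_treatment", ~targ_flag.values),
        ("no_pre_dx_sm_or_sact", ~predx_flag.values),
        ("age_18_plus", (rows["index_age"] >= 18).fillna(False).values),
        ("nsclc_sact_1l", nsclc_flag.values),
    ]

    failed = np.full(len(rows), "", dtype=object)
    surviving = np.ones(len(rows), dtype=bool)
    attrition = [("lung_cancer_dx", int(len(rows)))]
    for name, ok in checks:
        newly = surviving & ~np.asarray(ok)
        failed[newly] = name
        surviving &= np.asarray(ok)
        attrition.append((name, int(surviving.sum())))

    rows["eligible"] = surviving
    rows["failed_filter"] = failed
    rows = rows.drop(columns=["birth_year"])
    return rows.reset_index(drop=True), AttritionTable(attrition)


# -- baseline -----------------------------------------------------------


def baseline_table(ds: ClaimsDataset, cohort: pd.DataFrame,
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Baseline profile for every eligible patient.

    All flags derive only from claims in [index - lookback, index - 1];
    the index date itself is excluded.  nci_cci is the weighted sum of
    flagged Charlson conditions (the lung cancer itself is not scored).
    """
    config = config or AnalysisConfig()
    elig = cohort[cohort["eligible"]][["patient_id", "index_date"]]
    med = ds.medical_claims.merge(elig, on="patient_id", how="inner")
    look = pd.Timedelta(days=config.pre_dx_lookback_days)
    med = med[(med["service_date"] >= med["index_date"] - look)
              & (med["service_date"] < med["index_date"])]
    norm = _norm_dx_col(med)

    out = elig[["patient_id"]].copy().set_index("patient_id")

    def flag(prefixes) -> pd.Series:
        if not len(med):
            return pd.Series(False, index=out.index)
        hit = norm.str.contains(_prefix_pattern(prefixes))
        got = med.loc[hit, "patient_id"].unique()
        return pd.Series(out.index.isin(got), index=out.index)

    for name, prefixes in config.comorbidity_prefixes.items():
        out[name] = flag(prefixes)
    site_any = pd.Series(False, index=out.index)
    for site, prefixes in config.metastasis_site_prefixes.items():
        out[f"met_{site}"] = flag(prefixes)
        site_any |= out[f"met_{site}"]
    out["met_other"] = flag(config.metastasis_prefixes) & ~site_any
    out["smoking_history"] = flag(config.smoking_prefixes)

    weights = config.charlson_weights
    cci = np.zeros(len(out))
    for name, w in weights.items():
        if name in out.columns:
            cci += out[name].values * float(w)
    out["nci_cci"] = cci
    return out.reset_index()


def baseline_profile(ds: ClaimsDataset, patient_id: str,
                     index_date: pd.Timestamp,
                     config: AnalysisConfig | None = None) -> pd.Series:
    """Single-patient convenience wrapper around :func:`baseline_table`."""
    cohort = pd.DataFrame({"patient_id": [patient_id],
                           "index_date": [pd.Timestamp(index_date)],
                           "eligible": [True]})
    return baseline_table(ds, cohort, config).iloc[0]
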