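"""Claims data model and delimited-text I/O.

A :class:`ClaimsDataset` bundles the four claims tables (patients,
enrollment spans, medical claims, pharmacy claims) with a drug
dictionary.  The canonical on-disk form is plain CSV with a declared
header per table, ISO dates, and pipe-delimited diagnosis-code lists, so
fixtures stay inspectable with any text tool.

Reading validates row-level invariants; malformed rows are rejected and
counted (never silently dropped), while structural problems — a missing
table, a drug code that does not resolve in the dictionary — are fatal.
Enrollment spans are merged on read into maximal disjoint spans per
(patient, benefit-flag) combination, which preserves total covered days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .dictionary import DrugDictionary, UnknownDrugCodeError

PATIENT_COLS = ["patient_id", "birth_year", "sex", "region", "payer",
                "death_date"]
ENROLL_COLS = ["patient_id", "start_date", "end_date", "medical", "pharmacy"]
MED_COLS = ["claim_id", "patient_id", "service_date", "setting", "dx_codes",
            "drug_code", "paid_amount", "service_year"]
PHARM_COLS = ["claim_id", "patient_id", "fill_date", "drug_code",
              "days_supply", "paid_amount"]

TABLE_FILES = {
    "patients": "patients.csv",
    "enrollment": "enrollment.csv",
    "medical_claims": "medical_claims.csv",
    "pharmacy_claims": "pharmacy_claims.csv",
    "drug_dictionary": "drug_dictionary.csv",
}

SETTINGS = ("OUTPATIENT", "INPATIENT", "ED")

_EPOCH = np.datetime64("1970-01-01")


def to_days(series: pd.Series) -> np.ndarray:
    """Dates -> integer days since 1970-01-01 (NaT -> large sentinel)."""
    return (series.values.astype("datetime64[D]") - _EPOCH).astype("int64")


def days_to_ts(days) -> pd.Series:
    return pd.Series(np.asarray(days, dtype="int64")
                     .astype("datetime64[D]").astype("datetime64[ns]"))


@dataclass
class RejectionReport:
    """Per-(table, reason) counts of rows rejected during reading."""

    counts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["table", "reason", "count"]))

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum()) if len(self.counts) else 0

    def add(self, table: str, reason: str, n: int) -> None:
        if n:
            row = pd.DataFrame([{"table": table, "reason": reason,
                                 "count": int(n)}])
            self.counts = pd.concat([self.counts, row], ignore_index=True)


def merge_intervals(starts: np.ndarray, ends: np.ndarray,
                    gap_tolerance: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Merge integer-day intervals that overlap or abut within tolerance.

    Two spans merge when the next start is <= previous end + 1 +
    gap_tolerance.  Returns sorted, pairwise-disjoint intervals; the set
    of covered days (at tolerance 0) is invariant under the merge.
    """
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1] + 1 + gap_tolerance:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype="int64"), np.array(out_e, dtype="int64")


@dataclass
class ClaimsDataset:
    """The five validated tables every downstream stage consumes."""

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    medical_claims: pd.DataFrame
    pharmacy_claims: pd.DataFrame
    dictionary: DrugDictionary

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def equals(self, other: "ClaimsDataset") -> bool:
        def norm(df, keys):
            return df.sort_values(keys).reset_index(drop=True)

        return (
            norm(self.patients, ["patient_id"]).equals(
                norm(other.patients, ["patient_id"]))
            and norm(self.enrollment, ENROLL_COLS[:3]).equals(
                norm(other.enrollment, ENROLL_COLS[:3]))
            and norm(self.medical_claims, ["claim_id"]).equals(
                norm(other.medical_claims, ["claim_id"]))
            and norm(self.pharmacy_claims, ["claim_id"]).equals(
                norm(other.pharmacy_claims, ["claim_id"]))
        )


def _reject(df: pd.DataFrame, bad: pd.Series, report: RejectionReport,
            table: str, reason: str) -> pd.DataFrame:
    bad = bad.fillna(False).astype(bool)
    report.add(table, reason, int(bad.sum()))
    return df.loc[~bad]


def _clean_patients(df: pd.DataFrame, report: RejectionReport) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce")
    df = _reject(df, df["birth_year"].isna(), report, "patients",
                 "malformed birth_year")
    df["birth_year"] = df["birth_year"].astype(int)
    df = _reject(df, ~df["sex"].isin(["M", "F"]), report, "patients",
                 "invalid sex")
    df["death_date"] = pd.to_datetime(df.get("death_date"), errors="coerce")
    df = _reject(df, df["patient_id"].duplicated(keep="first"), report,
                 "patients", "duplicate patient_id")
    return df.reset_index(drop=True)


def _clean_enrollment(df: pd.DataFrame, report: RejectionReport,
                      gap_tolerance: int) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for c in ("start_date", "end_date"):
        df[c] = pd.to_datetime(df[c], errors="coerce")
    df = _reject(df, df["start_date"].isna() | df["end_date"].isna(),
                 report, "enrollment", "malformed date")
    df = _reject(df, df["end_date"] < df["start_date"], report,
                 "enrollment", "end before start")
    for c in ("medical", "pharmacy"):
        if df[c].dtype == object:
            df[c] = df[c].astype(str).str.strip().str.lower().isin(
                ["true", "1", "yes"])
        df[c] = df[c].astype(bool)
    # merge overlapping / abutting spans per (patient, benefit combo)
    merged = []
    for (pid, med, pharm), grp in df.groupby(
            ["patient_id", "medical", "pharmacy"], sort=True):
        s, e = merge_intervals(to_days(grp["start_date"]),
                               to_days(grp["end_date"]), gap_tolerance)
        merged.append(pd.DataFrame({
            "patient_id": pid, "start_date": days_to_ts(s).values,
            "end_date": days_to_ts(e).values, "medical": med,
            "pharmacy": pharm}))
    if merged:
        df = pd.concat(merged, ignore_index=True)
        df = df.sort_values(["patient_id", "start_date",
                             "end_date"]).reset_index(drop=True)
    else:
        df = df.reset_index(drop=True)
    return df[ENROLL_COLS]


def _clean_medical(df: pd.DataFrame, report: RejectionReport) -> pd.DataFrame:
    df = df.copy()
    for c in ("claim_id", "patient_id"):
        df[c] = df[c].astype(str)
    df["service_date"] = pd.to_datetime(df["service_date"], errors="coerce")
    df = _reject(df, df["service_date"].isna(), report, "medical_claims",
                 "malformed date")
    df = _reject(df, ~df["setting"].isin(SETTINGS), report,
                 "medical_claims", "invalid setting")
    df["dx_codes"] = df["dx_codes"].fillna("").astype(str)
    df["drug_code"] = df["drug_code"].fillna("").astype(str)
    df["paid_amount"] = pd.to_numeric(df["paid_amount"], errors="coerce")
    df = _reject(df, df["paid_amount"].isna() | (df["paid_amount"] < 0),
                 report, "medical_claims", "invalid paid_amount")
    df["service_year"] = df["service_date"].dt.year.astype(int)
    return df.reset_index(drop=True)[MED_COLS]


def _clean_pharmacy(df: pd.DataFrame, report: RejectionReport) -> pd.DataFrame:
    df = df.copy()
    for c in ("claim_id", "patient_id", "drug_code"):
        df[c] = df[c].astype(str)
    df["fill_date"] = pd.to_datetime(df["fill_date"], errors="coerce")
    df = _reject(df, df["fill_date"].isna(), report, "pharmacy_claims",
                 "malformed date")
    df["days_supply"] = pd.to_numeric(df["days_supply"], errors="coerce")
    df = _reject(df, df["days_supply"].isna() | (df["days_supply"] < 1),
                 report, "pharmacy_claims", "days_supply < 1")
    df["days_supply"] = df["days_supply"].astype(int)
    df["paid_amount"] = pd.to_numeric(df["paid_amount"], errors="coerce")
    df = _reject(df, df["paid_amount"].isna() | (df["paid_amount"] < 0),
                 report, "pharmacy_claims", "invalid paid_amount")
    return df.reset_index(drop=True)[PHARM_COLS]


def _resolve_paths(paths) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        return {k: base / v for k, v in TABLE_FILES.items()}
    return {k: Path(v) for k, v in paths.items()}


def read_dataset(paths, config: AnalysisConfig | None = None,
                 ) -> tuple[ClaimsDataset, RejectionReport]:
    """Read and validate the five tables.

    ``paths`` is a directory or a {table-name: path} map.  A missing
    required table is fatal; a missing drug dictionary falls back to the
    bundled default.  Returns the dataset plus a rejection report with
    one count per (table, reason).
    """
    config = config or AnalysisConfig()
    pmap = _resolve_paths(paths)
    for name in ("patients", "enrollment", "medical_claims",
                 "pharmacy_claims"):
        if not pmap[name].exists():
            raise FileNotFoundError(f"missing table file: {pmap[name]}")
    report = RejectionReport()

    patients = _clean_patients(
        pd.read_csv(pmap["patients"], dtype=str), report)
    enrollment = _clean_enrollment(
        pd.read_csv(pmap["enrollment"], dtype=str), report,
        config.enrollment_gap_tolerance_days)
    medical = _clean_medical(
        pd.read_csv(pmap["medical_claims"], dtype=str), report)
    pharmacy = _clean_pharmacy(
        pd.read_csv(pmap["pharmacy_claims"], dtype=str), report)

    if pmap["drug_dictionary"].exists():
        dictionary = DrugDictionary.from_csv(pmap["drug_dictionary"])
    else:
        dictionary = DrugDictionary.default()

    known = set(patients["patient_id"])
    for name, df in (("enrollment", enrollment),
                     ("medical_claims", medical),
                     ("pharmacy_claims", pharmacy)):
        orphan = ~df["patient_id"].isin(known)
        if orphan.any():
            report.add(name, "unknown patient_id", int(orphan.sum()))
    enrollment = enrollment[enrollment["patient_id"].isin(known)]
    medical = medical[medical["patient_id"].isin(known)]
    pharmacy = pharmacy[pharmacy["patient_id"].isin(known)]

    # every drug code must resolve; unresolvable codes could hide SACT
    codes = set(medical.loc[medical["drug_code"] != "", "drug_code"])
    codes |= set(pharmacy["drug_code"])
    unknown = [c for c in codes if c not in dictionary]
    if unknown:
        raise UnknownDrugCodeError(unknown)

    ds = ClaimsDataset(patients.reset_index(drop=True),
                       enrollment.reset_index(drop=True),
                       medical.reset_index(drop=True),
                       pharmacy.reset_index(drop=True), dictionary)
    return ds, report


def write_dataset(ds: ClaimsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the five tables as CSV; output re-reads to an equal dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pmap = {k: out / v for k, v in TABLE_FILES.items()}

    pat = ds.patients.copy()
    pat["death_date"] = pat["death_date"].dt.strftime("%Y-%m-%d")
    pat.to_csv(pmap["patients"], index=False)

    enr = ds.enrollment.copy()
    for c in ("start_date", "end_date"):
        enr[c] = enr[c].dt.strftime("%Y-%m-%d")
    enr.to_csv(pmap["enrollment"], index=False)

    med = ds.medical_claims.copy()
    med["service_date"] = med["service_date"].dt.strftime("%Y-%m-%d")
    med.to_csv(pmap["medical_claims"], index=False)

    pha = ds.pharmacy_claims.copy()
    pha["fill_date"] = pha["fill_date"].dt.strftime("%Y-%m-%d")
    pha.to_csv(pmap["pharmacy_claims"], index=False)

    ds.dictionary.to_frame().to_csv(pmap["drug_dictionary"], index=False)
    return pmap


def empty_dataset(dictionary: DrugDictionary | None = None) -> ClaimsDataset:
    """A structurally valid dataset with zero patients."""
    pat = pd.DataFrame(columns=PATIENT_COLS)
    pat = pat.astype({"birth_year": "int64"}, errors="ignore")
    pat["death_date"] = pd.to_datetime(pat["death_date"])
    enr = pd.DataFrame(columns=ENROLL_COLS)
    for c in ("start_date", "end_date"):
        enr[c] = pd.to_datetime(enr[c])
    for c in ("medical", "pharmacy"):
        enr[c] = enr[c].astype(bool)
    med = pd.DataFrame(columns=MED_COLS)
    med["service_date"] = pd.to_datetime(med["service_date"])
    med = med.astype({"paid_amount": "float64", "service_year": "int64"},
                     errors="ignore")
    pha = pd.DataFrame(columns=PHARM_COLS)
    pha["fill_date"] = pd.to_datetime(pha["fill_date"])
    pha = pha.astype({"days_supply": "int64", "paid_amount": "float64"},
                     errors="ignore")
    return ClaimsDataset(pat, enr, med, pha,
                         dictionary or DrugDictionary.default())
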