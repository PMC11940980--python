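"""Run configuration for the claims analysis pipeline.

All windows are integer day counts and all dates are ISO-8601 calendar
dates; duration arithmetic everywhere in the package is closed-form day
arithmetic (no time zones, no clock times).  The configuration also
carries the small reference tables the analysis needs: the medical-CPI
series used to restate paid amounts in reference-year dollars, the
NCI-adapted Charlson weights, and the ICD-10-CM prefix maps that define
diagnosis groups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

# Annual-average US medical-care CPI (BLS series CUUR0000SAM, 1982-84=100),
# rounded; bundled as a default so cost adjustment works out of the box.
# Any year present in the data must be present here (or be supplied by the
# caller's own table).
DEFAULT_MEDICAL_CPI: dict[int, float] = {
    2016: 463.7,
    2017: 475.3,
    2018: 484.7,
    2019: 498.4,
    2020: 518.9,
    2021: 521.5,
    2022: 546.8,
    2023: 553.0,
}

# NCI-adapted Charlson weights for the comorbidities this pipeline tracks.
# The index is a plain weighted sum over flagged conditions; the primary
# cancer itself is never scored.  Hypertension and anemia are tracked as
# baseline characteristics but are not Charlson conditions, so they carry
# no weight.  The table is data, not code: swap in another weighting by
# passing a different mapping.
DEFAULT_CHARLSON_WEIGHTS: dict[str, float] = {
    "coronary_heart_disease": 0.12624,
    "copd": 0.52487,
    "cerebrovascular_disease": 0.27868,
    "dementia": 0.72219,
    "diabetes": 0.29408,
    "chronic_kidney_disease": 0.60880,
    "chronic_liver_disease": 0.73803,
}

# ICD-10-CM prefix groups (dots ignored when matching).
DEFAULT_COMORBIDITY_PREFIXES: dict[str, tuple[str, ...]] = {
    "hypertension": ("I10", "I11", "I12", "I13", "I15", "I16"),
    "copd": ("J43", "J44"),
    "coronary_heart_disease": ("I20", "I21", "I22", "I24", "I25"),
    "anemia": ("D50", "D51", "D52", "D53", "D55", "D56", "D57", "D58",
               "D59", "D60", "D61", "D62", "D63", "D64"),
    "diabetes": ("E08", "E09", "E10", "E11", "E13"),
    "chronic_kidney_disease": ("N18",),
    "chronic_liver_disease": ("K70", "K72", "K73", "K74", "K76"),
    "dementia": ("F01", "F02", "F03", "G30"),
    "cerebrovascular_disease": ("I60", "I61", "I62", "I63", "I65", "I66",
                                "I67", "I69"),
}

DEFAULT_METASTASIS_SITE_PREFIXES: dict[str, tuple[str, ...]] = {
    "bone": ("C795",),
    "brain_spinal_cord": ("C793", "C794"),
    "liver": ("C787",),
}

# Maintenance-continuation rules: a maintenance-eligible drug introduced
# after the regimen window extends the current line (is "absorbed") when
# the regimen already contains a backbone of one of the listed classes.
# Keys are canonical drug ids first, drug classes as fallback.
DEFAULT_MAINTENANCE_BACKBONES: dict[str, tuple[str, ...]] = {
    "pemetrexed": ("PLATINUM",),
    "bevacizumab": ("PLATINUM", "NONPLAT_CHEMO"),
    "ICI": ("ICI", "PLATINUM"),
}


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


@dataclass
class AnalysisConfig:
    """Parameters of the cohort / line-of-therapy / cost analysis.

    Defaults reflect a study window of 2016-01-01 to 2023-03-31 with
    first-line starts restricted to 2020 onward, a 180-day pre-diagnosis
    lookback, a 30-day post-index enrollment requirement, a 30-day
    regimen-assembly window, a 60-day treatment-gap rule, and a 30-day
    tail appended to the last runout when delimiting the costing window.
    """

    study_start: date = date(2016, 1, 1)
    study_end: date = date(2023, 3, 31)
    index_floor: date = date(2020, 1, 1)
    pre_dx_lookback_days: int = 180
    post_index_enroll_days: int = 30
    regimen_window_days: int = 30
    gap_days: int = 60
    sact_period_tail_days: int = 30
    month_length_days: float = 30.4375
    enrollment_gap_tolerance_days: int = 0
    reference_year: int = 2022
    cpi_table: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDICAL_CPI))
    charlson_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHARLSON_WEIGHTS))
    lung_cancer_prefixes: tuple[str, ...] = ("C34",)
    metastasis_prefixes: tuple[str, ...] = ("C77", "C78", "C79")
    smoking_prefixes: tuple[str, ...] = ("F17",)
    comorbidity_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREFIXES))
    metastasis_site_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_METASTASIS_SITE_PREFIXES))
    maintenance_backbones: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MAINTENANCE_BACKBONES))
    # Non-SACT drugs still counted as lung-cancer-related medication when
    # flagging claims (supportive care); empty by default.
    nsclc_supportive_drugs: tuple[str, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pre_dx_lookback_days", "post_index_enroll_days",
                     "regimen_window_days", "gap_days",
                     "sact_period_tail_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.month_length_days <= 0:
            raise ValueError("month_length_days must be positive")
        if self.reference_year not in self.cpi_table:
            raise ValueError(
                f"cpi_table lacks the reference year {self.reference_year}")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("study_start", "study_end", "index_floor"):
            out[key] = out[key].isoformat()
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        for key in ("study_start", "study_end", "index_floor"):
            if key in raw:
                raw[key] = _parse_date(raw[key])
        if "cpi_table" in raw:
            raw["cpi_table"] = {int(k): float(v)
                                for k, v in raw["cpi_table"].items()}
        for key in ("lung_cancer_prefixes", "metastasis_prefixes",
                    "smoking_prefixes", "nsclc_supportive_drugs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("comorbidity_prefixes", "metastasis_site_prefixes",
                    "maintenance_backbones"):
            if key in raw:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def normalize_dx(code: str) -> str:
    """Normalize an ICD-10-CM code for prefix matching (strip the dot)."""
    return code.replace(".", "").strip().upper()


def matches_prefix(code: str, prefixes: tuple[str, ...]) -> bool:
    norm = normalize_dx(code)
    return any(norm.startswith(normalize_dx(p)) for p in prefixes)
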