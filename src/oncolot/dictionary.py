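"""Drug dictionary: maps drug codes to therapeutic classes.

The dictionary is data, not code.  The bundled default covers the common
systemic anticancer agents (checkpoint inhibitors, platinums, taxanes and
other chemotherapies, targeted agents, anti-angiogenics, SCLC-predominant
agents) plus a handful of non-oncology drugs, keyed by HCPCS/NDC-style
codes.  Cisplatin/carboplatin and paclitaxel/nab-paclitaxel share
substitution groups, so swapping one for the other never looks like a new
drug to the line-of-therapy engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

DRUG_CLASSES = ("ICI", "PLATINUM", "NONPLAT_CHEMO", "TARGETED", "VEGF",
                "SCLC_TYPICAL", "OTHER")
#: classes that count as systemic anticancer therapy
SACT_CLASSES = frozenset(
    {"ICI", "PLATINUM", "NONPLAT_CHEMO", "TARGETED", "VEGF", "SCLC_TYPICAL"})


class UnknownDrugCodeError(KeyError):
    """Raised when a drug code does not resolve in the dictionary."""

    def __init__(self, codes):
        self.codes = sorted(set(codes)) if not isinstance(codes, str) \
            else [codes]
        super().__init__(f"unknown drug code(s): {', '.join(self.codes)}")


@dataclass(frozen=True)
class DrugDictionaryEntry:
    drug_code: str
    generic_name: str
    drug_class: str
    substitution_group: str | None
    maintenance_eligible: bool
    default_runout_days: int

    @property
    def canonical_id(self) -> str:
        """Substitution group when present, else the generic name."""
        return self.substitution_group or self.generic_name


def is_sact(entry: DrugDictionaryEntry) -> bool:
    return entry.drug_class in SACT_CLASSES


class DrugDictionary:
    """One entry per drug code, with class and substitution metadata."""

    def __init__(self, entries: list[DrugDictionaryEntry]):
        self._by_code: dict[str, DrugDictionaryEntry] = {}
        for e in entries:
            if e.drug_class not in DRUG_CLASSES:
                raise ValueError(
                    f"{e.drug_code}: unknown drug_class {e.drug_class!r}")
            if e.default_runout_days < 1:
                raise ValueError(
                    f"{e.drug_code}: default_runout_days must be >= 1")
            if e.drug_code in self._by_code:
                raise ValueError(f"duplicate drug_code {e.drug_code!r}")
            self._by_code[e.drug_code] = e
        self._by_name = {e.generic_name: e for e in entries}

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def lookup(self, code: str) -> DrugDictionaryEntry:
        try:
            return self._by_code[code]
        except KeyError:
            raise UnknownDrugCodeError(code) from None

    def by_name(self, generic_name: str) -> DrugDictionaryEntry:
        try:
            return self._by_name[generic_name]
        except KeyError:
            raise UnknownDrugCodeError(generic_name) from None

    def entries(self) -> list[DrugDictionaryEntry]:
        return list(self._by_code.values())

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DrugDictionary":
        entries = []
        for row in df.itertuples(index=False):
            sub = row.substitution_group
            if sub is None or (isinstance(sub, float) and pd.isna(sub)) \
                    or sub == "":
                sub = None
            maint = row.maintenance_eligible
            if isinstance(maint, str):
                maint = maint.strip().lower() in ("true", "1", "yes")
            entries.append(DrugDictionaryEntry(
                drug_code=str(row.drug_code),
                generic_name=str(row.generic_name),
                drug_class=str(row.drug_class),
                substitution_group=sub,
                maintenance_eligible=bool(maint),
                default_runout_days=int(row.default_runout_days),
            ))
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "drug_code": e.drug_code,
                "generic_name": e.generic_name,
                "drug_class": e.drug_class,
                "substitution_group": e.substitution_group or "",
                "maintenance_eligible": e.maintenance_eligible,
                "default_runout_days": e.default_runout_days,
            } for e in self._by_code.values()]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        return cls.from_frame(pd.read_csv(path, dtype={"drug_code": str}))

    @classmethod
    def default(cls) -> "DrugDictionary":
        with resources.as_file(
                resources.files("oncolot.data") / "drug_dictionary.csv"
        ) as p:
            return cls.from_csv(p)


def lookup_drug(code: str, dictionary: DrugDictionary) -> DrugDictionaryEntry:
    """Resolve a drug code; raises :class:`UnknownDrugCodeError` if absent."""
    return dictionary.lookup(code)
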