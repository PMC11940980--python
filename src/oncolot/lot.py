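"""Line-of-therapy derivation and regimen classification.

A line of therapy (LOT) is reconstructed from dated drug claims.  Every
systemic anticancer (SACT) claim becomes a :class:`DrugEpisode` with a
runout date: fill date + days supply - 1 for pharmacy fills, service
date + a per-drug default runout (21 days, the dominant cycle length)
for infused drugs, which carry no days-supply on claims.  Episodes are
collapsed over substitution groups, so cisplatin/carboplatin (and the
taxane pair) are one canonical agent.

The first line opens at the first SACT on or after the metastasis date.
Every SACT in the 30-day window starting at the line's first day joins
the regimen.  After the window, each claim date is evaluated in order:

* gap rule first — if the claim starts >= 60 days after the maximum
  runout of everything in the current line, the line advances no matter
  which drug it is;
* a drug already in the regimen continues the line (pauses and
  reintroductions do not advance it);
* a maintenance-eligible drug whose backbone is present in the regimen
  is absorbed: it extends the line but leaves the regimen used for
  classification unchanged;
* any other new drug advances the line.

A line closes the day before the next line starts, or at the end of
continuous enrollment, the study end, or death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .dataset import ClaimsDataset, merge_intervals, to_days, days_to_ts
from .dictionary import DrugDictionary, SACT_CLASSES

CATEGORIES = ("ICI_MONO_DUAL", "ICI_PBCT", "ICI_NONPBCT", "PBCT_MONO_COMBO",
              "NONPBCT_MONO", "NONPBCT_COMBO", "OTHER")

# evaluate_event outcomes
CONTINUE = "CONTINUE"
ADVANCE_NEW_DRUG = "ADVANCE_NEW_DRUG"
ADVANCE_GAP = "ADVANCE_GAP"
ABSORB_MAINTENANCE = "ABSORB_MAINTENANCE"
ABSORB_SUBSTITUTION = "ABSORB_SUBSTITUTION"

END_REASONS = ("NEW_DRUG", "GAP", "ENROLLMENT_END", "STUDY_END", "DEATH",
               "FOLLOWUP_END")


@dataclass(frozen=True)
class DrugEpisode:
    patient_id: str
    drug_code: str
    canonical_id: str
    drug_class: str
    maintenance_eligible: bool
    start_day: int
    runout_day: int


@dataclass
class LotSegment:
    patient_id: str
    lot_number: int
    start_day: int
    end_day: int
    regimen: frozenset  # canonical ids
    category: str
    end_reason: str
    max_runout_day: int


def canonical_class_map(dictionary: DrugDictionary) -> dict[str, str]:
    """Canonical id -> drug class (consistent within substitution groups)."""
    return {e.canonical_id: e.drug_class for e in dictionary.entries()}


def build_episodes(ds: ClaimsDataset, patient_id: str,
                   from_date) -> list[DrugEpisode]:
    """Materialize a patient's SACT claims on/after ``from_date`` as
    episodes, sorted by start day then canonical id."""
    frame = episode_frame(ds)
    frame = frame[(frame["patient_id"] == patient_id)
                  & (frame["start_day"]
                     >= int(to_days(pd.Series([pd.Timestamp(from_date)]))[0]))]
    return _frame_to_episodes(frame)


def episode_frame(ds: ClaimsDataset) -> pd.DataFrame:
    """All SACT claims of the dataset as an episode table (vectorized)."""
    entries = {e.drug_code: e for e in ds.dictionary.entries()}
    cls = {c: e.drug_class for c, e in entries.items()}
    canon = {c: e.canonical_id for c, e in entries.items()}
    maint = {c: e.maintenance_eligible for c, e in entries.items()}
    runout = {c: e.default_runout_days for c, e in entries.items()}

    med = ds.medical_claims[ds.medical_claims["drug_code"] != ""]
    med_cls = med["drug_code"].map(cls)
    med = med[med_cls.isin(SACT_CLASSES)]
    med_days = to_days(med["service_date"])
    med_f = pd.DataFrame({
        "patient_id": med["patient_id"].values,
        "drug_code": med["drug_code"].values,
        "start_day": med_days,
        "runout_day": med_days
        + med["drug_code"].map(runout).values.astype(int) - 1,
    })

    pha = ds.pharmacy_claims
    pha_cls = pha["drug_code"].map(cls)
    pha = pha[pha_cls.isin(SACT_CLASSES)]
    pha_days = to_days(pha["fill_date"])
    pha_f = pd.DataFrame({
        "patient_id": pha["patient_id"].values,
        "drug_code": pha["drug_code"].values,
        "start_day": pha_days,
        "runout_day": pha_days + pha["days_supply"].values.astype(int) - 1,
    })

    frame = pd.concat([med_f, pha_f], ignore_index=True)
    frame["canonical_id"] = frame["drug_code"].map(canon)
    frame["drug_class"] = frame["drug_code"].map(cls)
    frame["maintenance_eligible"] = frame["drug_code"].map(maint)
    return frame.sort_values(
        ["patient_id", "start_day", "canonical_id"]).reset_index(drop=True)


def _frame_to_episodes(frame: pd.DataFrame) -> list[DrugEpisode]:
    return [DrugEpisode(r.patient_id, r.drug_code, r.canonical_id,
                        r.drug_class, bool(r.maintenance_eligible),
                        int(r.start_day), int(r.runout_day))
            for r in frame.itertuples(index=False)]


def assemble_initial_regimen(episodes: list[DrugEpisode], lot_start: int,
                             config: AnalysisConfig | None = None,
                             ) -> frozenset:
    """Canonical ids of episodes starting in [lot_start, lot_start+29]."""
    config = config or AnalysisConfig()
    end = lot_start + config.regimen_window_days - 1
    return frozenset(e.canonical_id for e in episodes
                     if lot_start <= e.start_day <= end)


def _maintenance_absorbable(episode: DrugEpisode, regimen_classes: set[str],
                            config: AnalysisConfig) -> bool:
    if not episode.maintenance_eligible:
        return False
    rules = config.maintenance_backbones
    required = rules.get(episode.canonical_id,
                         rules.get(episode.drug_class))
    if not required:
        return False
    return bool(regimen_classes & set(required))


def evaluate_event(current: LotSegment, episode: DrugEpisode,
                   dictionary: DrugDictionary,
                   config: AnalysisConfig | None = None) -> str:
    """Decide how one post-window episode affects the current line.

    The gap rule is checked first and fires regardless of drug identity;
    otherwise an in-regimen drug continues the line, an absorbable
    maintenance drug extends it, and anything else advances it.
    """
    config = config or AnalysisConfig()
    if episode.start_day - current.max_runout_day >= config.gap_days:
        return ADVANCE_GAP
    if episode.canonical_id in current.regimen:
        return CONTINUE
    cmap = canonical_class_map(dictionary)
    regimen_classes = {cmap[c] for c in current.regimen if c in cmap}
    if _maintenance_absorbable(episode, regimen_classes, config):
        return ABSORB_MAINTENANCE
    return ADVANCE_NEW_DRUG


def classify_regimen(regimen: frozenset,
                     dictionary: DrugDictionary) -> str:
    """Map a regimen's canonical agents to a treatment category.

    Anti-angiogenic (VEGF) agents never change an otherwise-determined
    category; a regimen that is only VEGF (or contains targeted therapy,
    or is empty after dropping VEGF) falls into OTHER.
    """
    cmap = canonical_class_map(dictionary)
    classes = [cmap.get(c, "OTHER") for c in regimen]
    core = [c for c in classes if c != "VEGF"]
    if not core or "TARGETED" in core:
        return "OTHER"
    n_ici = sum(c == "ICI" for c in core)
    has_plat = any(c == "PLATINUM" for c in core)
    # SCLC-predominant agents count as non-platinum chemotherapy here
    n_chemo = sum(c in ("NONPLAT_CHEMO", "SCLC_TYPICAL") for c in core)
    has_vegf = len(core) < len(classes)
    if has_vegf and not has_plat and not n_chemo:
        # VEGF + ICI without chemotherapy is not a named category
        return "OTHER"
    if n_ici and has_plat:
        return "ICI_PBCT"
    if n_ici and n_chemo:
        return "ICI_NONPBCT"
    if n_ici and not has_plat and not n_chemo:
        return "ICI_MONO_DUAL" if n_ici <= 2 else "OTHER"
    if has_plat:
        return "PBCT_MONO_COMBO"
    if n_chemo == 1:
        return "NONPBCT_MONO"
    if n_chemo >= 2:
        return "NONPBCT_COMBO"
    return "OTHER"


def _derive_one(episodes: list[DrugEpisode], lot1_start: int, bound_day: int,
                bound_reason: str, config: AnalysisConfig,
                cmap: dict[str, str]) -> list[LotSegment]:
    """Sequential scan turning one patient's episodes into segments.

    ``episodes`` must be sorted, start at or after the first-line start,
    and contain nothing after ``bound_day``.
    """
    segments: list[LotSegment] = []
    i = 0
    n = len(episodes)
    lot_number = 1
    window = config.regimen_window_days - 1
    pid = episodes[0].patient_id if n else ""

    while i < n:
        start = episodes[i].start_day
        win_end = start + window
        regimen: set[str] = set()
        max_runout = start
        # regimen window: everything inside joins the regimen
        while i < n and episodes[i].start_day <= win_end:
            regimen.add(episodes[i].canonical_id)
            max_runout = max(max_runout, episodes[i].runout_day)
            i += 1
        regimen_classes = {cmap[c] for c in regimen if c in cmap}
        advance_at = None
        reason = None
        while i < n:
            d = episodes[i].start_day
            group = []
            j = i
            while j < n and episodes[j].start_day == d:
                group.append(episodes[j])
                j += 1
            if d - max_runout >= config.gap_days:
                advance_at, reason = d, "GAP"
                break
            new_drug = False
            for ep in group:
                if ep.canonical_id in regimen:
                    continue
                if _maintenance_absorbable(ep, regimen_classes, config):
                    continue
                new_drug = True
            if new_drug:
                advance_at, reason = d, "NEW_DRUG"
                break
            for ep in group:
                max_runout = max(max_runout, ep.runout_day)
            i = j
        if advance_at is not None:
            end_day = advance_at - 1
        else:
            end_day = max(start, bound_day)
            reason = bound_reason
        segments.append(LotSegment(
            patient_id=pid, lot_number=lot_number, start_day=start,
            end_day=end_day, regimen=frozenset(regimen),
            category="", end_reason=reason, max_runout_day=max_runout))
        lot_number += 1
    return segments


def _followup_bound(ds: ClaimsDataset, config: AnalysisConfig,
                    ) -> dict[str, int]:
    """Per patient: end day of the continuous dual-benefit enrollment
    span containing each patient's coverage (max merged end)."""
    tol = config.enrollment_gap_tolerance_days
    out: dict[str, list] = {}
    for pid, grp in ds.enrollment.groupby("patient_id", sort=False):
        med = grp[grp["medical"]]
        pha = grp[grp["pharmacy"]]
        ms, me = merge_intervals(to_days(med["start_date"]),
                                 to_days(med["end_date"]), tol)
        ps, pe = merge_intervals(to_days(pha["start_date"]),
                                 to_days(pha["end_date"]), tol)
        out[pid] = (ms, me, ps, pe)
    return out


def _span_end_containing(spans, day: int) -> int | None:
    ms, me, ps, pe = spans
    end = None
    mi = np.searchsorted(ms, day, side="right") - 1
    pi = np.searchsorted(ps, day, side="right") - 1
    if mi >= 0 and me[mi] >= day and pi >= 0 and pe[pi] >= day:
        end = int(min(me[mi], pe[pi]))
    return end


def followup_bounds(ds: ClaimsDataset, cohort: pd.DataFrame,
                    config: AnalysisConfig | None = None,
                    ) -> dict[str, tuple[int, str]]:
    """Per eligible patient: follow-up end day and its reason.

    Follow-up ends at the earliest of the end of the continuous
    dual-benefit enrollment span containing the index date, the study
    end, or death.
    """
    config = config or AnalysisConfig()
    study_end = int(to_days(pd.Series([pd.Timestamp(config.study_end)]))[0])
    elig = cohort[cohort["eligible"]]
    index_days = dict(zip(elig["patient_id"], to_days(elig["index_date"])))
    death = ds.patients.set_index("patient_id")["death_date"]
    death_days = {}
    if len(death):
        dd = to_days(death)
        for pid, d, raw in zip(death.index, dd, death.values):
            if not pd.isna(raw):
                death_days[pid] = int(d)
    spans = _followup_bound(ds, config)
    out = {}
    for pid, idx_day in index_days.items():
        enroll_end = _span_end_containing(spans[pid], int(idx_day)) \
            if pid in spans else None
        bound, reason = study_end, "STUDY_END"
        if enroll_end is not None and enroll_end < bound:
            bound, reason = enroll_end, "ENROLLMENT_END"
        dd = death_days.get(pid)
        if dd is not None and dd < bound:
            bound, reason = dd, "DEATH"
        out[pid] = (bound, reason)
    return out


def derive_all_lots(ds: ClaimsDataset, cohort: pd.DataFrame,
                    config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Derive LOT segments for every eligible cohort patient.

    Returns one row per segment: patient_id, lot_number, start/end dates,
    pipe-delimited regimen, category, end_reason, max_runout_date.
    """
    config = config or AnalysisConfig()
    cmap = canonical_class_map(ds.dictionary)

    elig = cohort[cohort["eligible"]]
    index_days = dict(zip(elig["patient_id"], to_days(elig["index_date"])))
    bounds = followup_bounds(ds, cohort, config)

    frame = episode_frame(ds)
    frame = frame[frame["patient_id"].isin(index_days.keys())]
    groups = dict(tuple(frame.groupby("patient_id", sort=False)))

    records = []
    for pid, idx_day in index_days.items():
        grp = groups.get(pid)
        if grp is None:
            continue
        bound, reason = bounds[pid]
        sub = grp[(grp["start_day"] >= idx_day)
                  & (grp["start_day"] <= bound)]
        if not len(sub):
            continue
        episodes = _frame_to_episodes(sub)
        segs = _derive_one(episodes, int(idx_day), bound, reason,
                           config, cmap)
        for s in segs:
            records.append({
                "patient_id": pid,
                "lot_number": s.lot_number,
                "start_day": s.start_day,
                "end_day": s.end_day,
                "regimen": "|".join(sorted(s.regimen)),
                "category": classify_regimen(s.regimen, ds.dictionary),
                "end_reason": s.end_reason,
                "max_runout_day": s.max_runout_day,
            })
    lots = pd.DataFrame(records, columns=[
        "patient_id", "lot_number", "start_day", "end_day", "regimen",
        "category", "end_reason", "max_runout_day"])
    for c in ("start", "end", "max_runout"):
        lots[f"{c}_date"] = days_to_ts(lots[f"{c}_day"]).values \
            if len(lots) else pd.to_datetime(pd.Series([], dtype="object"))
    return lots


def derive_lots(ds: ClaimsDataset, cohort_row: pd.Series,
                config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Segments for a single eligible cohort row (see derive_all_lots)."""
    cohort = pd.DataFrame([{
        "patient_id": cohort_row["patient_id"],
        "index_date": cohort_row["index_date"],
        "eligible": True}])
    return derive_all_lots(ds, cohort, config)
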