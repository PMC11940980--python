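"""First-line duration, time to next treatment, and the costing window.

Durations are inclusive day counts.  The first line's duration runs from
the index date to the earliest of: the maximum runout of every agent in
the line, the day before the next line starts, or the end of follow-up
(end of enrollment, study end, or death).  An end imposed by follow-up
or study end — rather than by runout, a next line, or death — is a
censored observation, and the pooled duration distribution is therefore
summarized with the Kaplan–Meier product-limit estimator.

Time to next treatment (TTNT) is the day count from the first-line start
through the day before the second line starts, reported as a plain mean
over patients who actually received a second line.

The SACT period — the window over which utilization and costs are
attributed — runs from the index date to the earliest of (max runout +
30 days), the day before the second line, or the end of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .config import AnalysisConfig


@dataclass
class KMCurve:
    """Product-limit estimate: survival at each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_days: float | None

    def median_months(self, month_length_days: float = 30.4375
                      ) -> float | None:
        if self.median_days is None:
            return None
        return self.median_days / month_length_days


def _lot1_lot2(lots: pd.DataFrame) -> pd.DataFrame:
    l1 = lots[lots["lot_number"] == 1][
        ["patient_id", "start_day", "end_day", "max_runout_day",
         "category", "end_reason"]].rename(columns={
             "start_day": "l1_start", "end_day": "l1_end",
             "max_runout_day": "l1_runout"})
    l2 = lots[lots["lot_number"] == 2][["patient_id", "start_day"]] \
        .rename(columns={"start_day": "l2_start"})
    return l1.merge(l2, on="patient_id", how="left")


def duration_table(lots: pd.DataFrame) -> pd.DataFrame:
    """One censored duration observation per treated patient.

    duration_days = min(max runout, segment end) - start + 1; the
    observation is censored when the segment end was imposed by the end
    of follow-up or of the study while therapy was still running out.
    """
    m = _lot1_lot2(lots)
    end = np.minimum(m["l1_runout"].values, m["l1_end"].values)
    duration = end - m["l1_start"].values + 1
    if (duration < 0).any():
        raise ValueError("negative first-line duration; upstream "
                         "segment invariant violated")
    censored = (m["l1_end"].values < m["l1_runout"].values) \
        & m["end_reason"].isin(
            ["STUDY_END", "ENROLLMENT_END", "FOLLOWUP_END"]).values
    return pd.DataFrame({
        "patient_id": m["patient_id"],
        "category": m["category"],
        "duration_days": duration.astype(int),
        "censored": censored,
    })


def compute_duration(seg1: pd.Series) -> tuple[int, bool]:
    """Single-segment convenience form of :func:`duration_table`."""
    one = duration_table(pd.DataFrame([{
        "patient_id": seg1.get("patient_id", "p"),
        "lot_number": 1,
        "start_day": seg1["start_day"],
        "end_day": seg1["end_day"],
        "max_runout_day": seg1["max_runout_day"],
        "category": seg1.get("category", ""),
        "end_reason": seg1["end_reason"],
    }])).iloc[0]
    return int(one["duration_days"]), bool(one["censored"])


def ttnt_table(lots: pd.DataFrame) -> pd.DataFrame:
    """Days from first-line start through the day before the second line,
    for patients with a second line only."""
    m = _lot1_lot2(lots)
    m = m[m["l2_start"].notna()]
    ttnt = (m["l2_start"].astype(int) - m["l1_start"]).astype(int)
    return pd.DataFrame({"patient_id": m["patient_id"],
                         "category": m["category"],
                         "ttnt_days": ttnt.values})


def sact_period_table(lots: pd.DataFrame,
                      bounds: dict[str, tuple[int, str]],
                      config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Costing window per treated patient (start_day/end_day inclusive)."""
    config = config or AnalysisConfig()
    m = _lot1_lot2(lots)
    bound = m["patient_id"].map({p: b for p, (b, _) in bounds.items()})
    end = np.minimum(m["l1_runout"].values + config.sact_period_tail_days,
                     bound.values.astype(float))
    has2 = m["l2_start"].notna().values
    end = np.where(has2, np.minimum(end, m["l2_start"].values - 1), end)
    end = np.maximum(end, m["l1_start"].values).astype(int)
    return pd.DataFrame({"patient_id": m["patient_id"],
                         "category": m["category"],
                         "start_day": m["l1_start"].values,
                         "end_day": end})


def km_fit(records: pd.DataFrame) -> KMCurve:
    """Product-limit estimator over a duration table.

    Expects columns duration_days and censored.  The median is the
    smallest event time at which survival is <= 0.5 (no interpolation);
    it is None when survival never reaches 0.5.
    """
    if not len(records):
        raise ValueError("km_fit requires at least one duration record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["duration_days"].values,
            event_observed=~records["censored"].values)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index].iloc[:, 0].to_numpy()
    at_risk = ev["at_risk"].to_numpy()
    below = surv <= 0.5 + 1e-12
    median = float(times[below][0]) if below.any() else None
    return KMCurve(times, surv, at_risk, median)


def km_by_category(durations: pd.DataFrame) -> dict[str, KMCurve]:
    """Pooled plus per-category product-limit estimates."""
    out = {"ALL": km_fit(durations)}
    for cat, grp in durations.groupby("category"):
        out[str(cat)] = km_fit(grp)
    return out


def km_curve_frame(curves: dict[str, KMCurve]) -> pd.DataFrame:
    rows = []
    for name, c in curves.items():
        for t, s, r in zip(c.event_times, c.survival, c.at_risk):
            rows.append({"group": name, "time_days": t, "survival": s,
                         "at_risk": int(r)})
    return pd.DataFrame(rows, columns=["group", "time_days", "survival",
                                       "at_risk"])
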