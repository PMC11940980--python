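"""Duration conventions, product-limit estimation, TTNT, SACT period."""

import numpy as np
import pandas as pd
import pytest

from oncolot.config import AnalysisConfig
from oncolot.outcomes import (duration_table, km_fit, sact_period_table,
                              ttnt_table)


def lots_frame(rows):
    """Minimal LOT segment frame from (patient, lot, start, end, runout,
    reason) tuples."""
    return pd.DataFrame([{
        "patient_id": p, "lot_number": k, "start_day": s, "end_day": e,
        "max_runout_day": r, "category": "ICI_PBCT", "end_reason": reason,
        "regimen": "pembrolizumab"}
        for p, k, s, e, r, reason in rows])


def naive_km(durations, events):
    """Independent product-limit oracle: recompute the risk set from
    scratch at every distinct event time."""
    durations = np.asarray(durations)
    events = np.asarray(events)
    times = np.unique(durations[events])
    surv = []
    s = 1.0
    for t in times:
        n_at_risk = int((durations >= t).sum())
        d = int(((durations == t) & events).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    surv = np.array(surv)
    below = surv <= 0.5 + 1e-12
    median = float(times[below][0]) if below.any() else None
    return times, surv, median


class TestDuration:
    def test_runout_end_is_inclusive_day_count(self):
        # runout on day 180 (start day 0), no next line, far study end
        lots = lots_frame([("p", 1, 0, 5000, 180, "STUDY_END")])
        rec = duration_table(lots).iloc[0]
        assert rec["duration_days"] == 181
        assert not rec["censored"]

    def test_next_line_truncates_uncensored(self):
        lots = lots_frame([("p", 1, 0, 119, 200, "NEW_DRUG"),
                           ("p", 2, 120, 300, 300, "STUDY_END")])
        rec = duration_table(lots).iloc[0]
        assert rec["duration_days"] == 120  # through day 119 inclusive
        assert not rec["censored"]

    def test_enrollment_end_before_runout_censors(self):
        lots = lots_frame([("p", 1, 0, 90, 200, "ENROLLMENT_END")])
        rec = duration_table(lots).iloc[0]
        assert rec["duration_days"] == 91
        assert rec["censored"]

    def test_death_end_is_an_event(self):
        lots = lots_frame([("p", 1, 0, 90, 200, "DEATH")])
        rec = duration_table(lots).iloc[0]
        assert not rec["censored"]


class TestKaplanMeier:
    def test_uncensored_median(self):
        rec = pd.DataFrame({"duration_days": [2, 4, 6],
                            "censored": [False] * 3})
        assert km_fit(rec).median_days == 4

    def test_hand_computed_product_limit(self):
        rec = pd.DataFrame({"duration_days": [1, 2, 3],
                            "censored": [False, True, False]})
        km = km_fit(rec)
        assert list(km.event_times) == [1, 3]
        assert km.survival == pytest.approx([2 / 3, 0.0])
        assert km.median_days == 3

    def test_all_censored_has_no_median(self):
        rec = pd.DataFrame({"duration_days": [5, 7],
                            "censored": [True, True]})
        km = km_fit(rec)
        assert km.median_days is None
        assert len(km.event_times) == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_fit(pd.DataFrame({"duration_days": [], "censored": []}))

    def test_uncensored_km_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        dur = rng.integers(1, 40, 60)
        rec = pd.DataFrame({"duration_days": dur,
                            "censored": [False] * 60})
        km = km_fit(rec)
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((dur > t).mean())

    def test_matches_naive_oracle_on_random_inputs(self):
        """Product-limit output equals a from-scratch risk-set
        recomputation on 100 random censored samples."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(1, 51))
            dur = rng.integers(1, 30, n)
            ev = rng.random(n) < 0.7
            if not ev.any():
                ev[0] = True
            rec = pd.DataFrame({"duration_days": dur, "censored": ~ev})
            km = km_fit(rec)
            t0, s0, m0 = naive_km(dur, ev)
            assert np.array_equal(km.event_times, t0)
            assert km.survival == pytest.approx(s0)
            assert km.median_days == m0


class TestTtnt:
    def test_day_count_through_day_before_second_line(self):
        lots = lots_frame([("p", 1, 0, 243, 150, "NEW_DRUG"),
                           ("p", 2, 244, 400, 400, "STUDY_END")])
        assert ttnt_table(lots).iloc[0]["ttnt_days"] == 244

    def test_absent_without_second_line(self):
        lots = lots_frame([("p", 1, 0, 300, 150, "STUDY_END")])
        assert len(ttnt_table(lots)) == 0

    def test_degenerate_next_day_second_line(self):
        lots = lots_frame([("p", 1, 0, 0, 20, "NEW_DRUG"),
                           ("p", 2, 1, 100, 100, "STUDY_END")])
        assert ttnt_table(lots).iloc[0]["ttnt_days"] == 1


class TestSactPeriod:
    def test_tail_after_runout(self):
        lots = lots_frame([("p", 1, 0, 500, 100, "STUDY_END")])
        per = sact_period_table(lots, {"p": (500, "STUDY_END")})
        assert per.iloc[0]["end_day"] == 130

    def test_second_line_truncates_to_day_before(self):
        lots = lots_frame([("p", 1, 0, 109, 100, "NEW_DRUG"),
                           ("p", 2, 110, 400, 400, "STUDY_END")])
        per = sact_period_table(lots, {"p": (500, "STUDY_END")})
        assert per.iloc[0]["end_day"] == 109

    def test_followup_end_wins_when_earliest(self):
        lots = lots_frame([("p", 1, 0, 90, 100, "ENROLLMENT_END")])
        per = sact_period_table(lots, {"p": (90, "ENROLLMENT_END")})
        assert per.iloc[0]["end_day"] == 90

    def test_period_always_within_index_and_followup(self, sim_small):
        from oncolot.cohort import build_cohort
        from oncolot.lot import derive_all_lots, followup_bounds
        _, ds, _ = sim_small
        cohort, _ = build_cohort(ds)
        lots = derive_all_lots(ds, cohort)
        bounds = followup_bounds(ds, cohort)
        per = sact_period_table(lots, bounds)
        bound = per["patient_id"].map({p: b for p, (b, _) in
                                       bounds.items()})
        assert (per["end_day"] >= per["start_day"]).all()
        assert (per["end_day"] <= bound).all()
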