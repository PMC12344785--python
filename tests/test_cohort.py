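"""Eligibility, follow-up windows, and person-month expansion."""

import numpy as np
import pandas as pd
import pytest

from ccw.cohort import (
    EligibilitySpec,
    FollowupWindow,
    apply_eligibility,
    build_followup_window,
    expand_person_months,
)


def person(pid=1, age=30.0, index="2012-06-01", death=None, emig=None):
    return pd.Series(
        {
            "person_id": pid,
            "age_at_index": age,
            "index_date": pd.Timestamp(index),
            "death_date": pd.Timestamp(death) if death else pd.NaT,
            "emigration_date": pd.Timestamp(emig) if emig else pd.NaT,
        }
    )


def persons_frame(rows):
    return pd.DataFrame(rows)


class TestEligibility:
    def test_age_washout_and_log_order(self):
        persons = persons_frame(
            [
                {"person_id": 1, "age_at_index": 5.0, "index_date": pd.Timestamp("2010-01-01")},
                {"person_id": 2, "age_at_index": 30.0, "index_date": pd.Timestamp("2010-01-01")},
                {"person_id": 3, "age_at_index": 40.0, "index_date": pd.Timestamp("2010-01-01")},
            ]
        )
        disp = pd.DataFrame(
            {
                "person_id": [3],
                "date": [pd.Timestamp("2009-01-01")],  # 12 months before index
                "drug_class": ["stimulant"],
                "days_supply": [30],
            }
        )
        eligible, log = apply_eligibility(persons, disp, EligibilitySpec())
        assert list(eligible["person_id"]) == [2]
        assert list(log["criterion"]) == [
            "assessed",
            "age_out_of_range",
            "outside_enrolment_window",
            "washout_violation",
            "eligible",
        ]
        assert log.set_index("criterion").loc["age_out_of_range", "n"] == 1
        assert log.set_index("criterion").loc["washout_violation", "n"] == 1

    def test_dispensation_outside_washout_window_is_allowed(self):
        persons = persons_frame([{"person_id": 1, "age_at_index": 30.0, "index_date": pd.Timestamp("2010-01-01")}])
        disp = pd.DataFrame(
            {
                "person_id": [1],
                "date": [pd.Timestamp("2010-01-01") - pd.Timedelta(days=19 * 30)],
                "drug_class": ["stimulant"],
                "days_supply": [30],
            }
        )
        eligible, _ = apply_eligibility(persons, disp, EligibilitySpec(washout_months=18))
        assert len(eligible) == 1

    def test_subcohort_age_bound(self):
        persons = persons_frame([{"person_id": 1, "age_at_index": 12.0, "index_date": pd.Timestamp("2010-01-01")}])
        eligible, _ = apply_eligibility(persons, pd.DataFrame(), EligibilitySpec(subcohort_age_min=15))
        assert len(eligible) == 0

    def test_missing_index_date_rejected(self):
        persons = persons_frame([{"person_id": 1, "age_at_index": 30.0, "index_date": pd.NaT}])
        with pytest.raises(ValueError, match="index_date"):
            apply_eligibility(persons, pd.DataFrame(), EligibilitySpec())


class TestFollowupWindow:
    def test_horizon_when_nothing_intervenes(self):
        w = build_followup_window(person(), pd.DataFrame(), "x", 24, "2020-12-31")
        assert w.end_reason == "horizon"
        assert (w.end - w.start).days == 720

    def test_event_terminates_when_stop_at_event(self):
        ev = pd.DataFrame({"person_id": [1], "date": [pd.Timestamp("2012-06-01") + pd.Timedelta(days=155)], "outcome_type": ["x"]})
        w = build_followup_window(person(), ev, "x", 24, "2020-12-31", stop_at_event=True)
        assert w.end_reason == "event"
        w2 = build_followup_window(person(), ev, "x", 24, "2020-12-31", stop_at_event=False)
        assert w2.end_reason == "horizon"

    def test_death_and_admin_end(self):
        w = build_followup_window(person(death="2012-10-01"), pd.DataFrame(), "x", 24, "2020-12-31")
        assert w.end_reason == "death"
        w2 = build_followup_window(person(index="2020-06-01"), pd.DataFrame(), "x", 24, "2020-12-31")
        assert w2.end_reason == "admin_end"

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            build_followup_window(person(), pd.DataFrame(), "x", 0, "2020-12-31")


class TestExpansion:
    def test_full_horizon_expansion_person_time(self):
        w = FollowupWindow(1, pd.Timestamp("2012-06-01"), pd.Timestamp("2012-06-01") + pd.Timedelta(days=720), "horizon")
        panel = expand_person_months(person(), w, pd.DataFrame())
        assert len(panel) == 24
        assert panel["event"].sum() == 0
        assert panel["person_years"].sum() == pytest.approx(2.0)

    def test_event_mid_interval_seven(self):
        # event on day 225 (interval 7): 8 rows, event flagged on the last
        start = pd.Timestamp("2012-06-01")
        ev = pd.DataFrame({"person_id": [1], "date": [start + pd.Timedelta(days=225)], "outcome_type": ["x"]})
        w = build_followup_window(person(), ev, "x", 24, "2020-12-31")
        panel = expand_person_months(person(), w, ev, outcome_type="x")
        assert len(panel) == 8
        assert panel["event"].iloc[7] == 1
        assert panel["event"].iloc[:7].sum() == 0
        # partial final interval: 16 of 30 days
        assert panel["person_years"].iloc[7] == pytest.approx(16 / 30 / 12)

    def test_boundary_day_belongs_to_later_interval(self):
        start = pd.Timestamp("2012-06-01")
        ev = pd.DataFrame({"person_id": [1], "date": [start + pd.Timedelta(days=60)], "outcome_type": ["x"]})
        w = build_followup_window(person(), ev, "x", 24, "2020-12-31")
        panel = expand_person_months(person(), w, ev, outcome_type="x")
        assert panel["event"].iloc[2] == 1 and len(panel) == 3

    def test_recurrent_mode_caps_one_event_per_interval(self):
        start = pd.Timestamp("2012-06-01")
        days = [95, 100, 110, 290]  # three events in interval 3, one in interval 9
        ev = pd.DataFrame({"person_id": [1] * 4, "date": [start + pd.Timedelta(days=d) for d in days], "outcome_type": ["x"] * 4})
        w = build_followup_window(person(), ev, "x", 24, "2020-12-31", stop_at_event=False)
        panel = expand_person_months(person(), w, ev, outcome_type="x", recurrent=True)
        assert panel["event"].sum() == 2
        assert panel.loc[panel["t"] == 3, "event"].item() == 1
        assert panel.loc[panel["t"] == 9, "event"].item() == 1

    def test_lagged_covariate_never_uses_current_interval(self):
        start = pd.Timestamp("2012-06-01")
        hist = pd.DataFrame({"person_id": [1, 1], "date": [start + pd.Timedelta(days=45), start - pd.Timedelta(days=10)], "code": ["tv", "tv"]})
        w = FollowupWindow(1, start, start + pd.Timedelta(days=120), "horizon")
        panel = expand_person_months(person(), w, pd.DataFrame(), covariate_history=hist)
        # record at day 45 (interval 1) shows up at interval 2; the pre-index
        # record (interval -1) feeds interval 0
        assert list(panel["tv_lag1"]) == [1.0, 0.0, 1.0, 0.0]
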