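"""Outcome model, weighted rates, cumulative incidence, recurrent panels."""

import numpy as np
import pandas as pd
import pytest

import ccw
from ccw.clone_censor import ARM_INITIATION, ARM_NON_INITIATION, TrialSpec
from ccw.estimation import (
    cumulative_incidence_curve,
    fit_outcome_model,
    prepare_recurrent_panel,
    weighted_incidence_rate,
)

from conftest import panel_from_arrays


def one_stratum_panel(ev_a=10, n_a=100, ev_b=5, n_b=100, weight=None):
    n = n_a + n_b
    event = np.concatenate([np.ones(ev_a), np.zeros(n_a - ev_a), np.ones(ev_b), np.zeros(n_b - ev_b)]).astype(int)
    arm = [ARM_INITIATION] * n_a + [ARM_NON_INITIATION] * n_b
    panel = panel_from_arrays(np.zeros(n, dtype=int), event, np.zeros(n, dtype=int), arm=arm, person=np.arange(n))
    panel["weight"] = np.ones(n) if weight is None else weight
    return panel


class TestOutcomeModel:
    def test_saturated_single_stratum_equals_closed_form_odds_ratio(self):
        res = fit_outcome_model(one_stratum_panel())
        expected = (10 / 90) / (5 / 95)
        assert res.irr == pytest.approx(expected, abs=1e-6)

    def test_exchangeable_arms_give_unity(self):
        res = fit_outcome_model(one_stratum_panel(ev_a=7, ev_b=7))
        assert res.irr == pytest.approx(1.0, abs=1e-9)

    def test_doubling_weights_leaves_estimate_unchanged(self):
        a = fit_outcome_model(one_stratum_panel())
        b = fit_outcome_model(one_stratum_panel(weight=np.full(200, 2.0)))
        assert a.irr == pytest.approx(b.irr, abs=1e-10)

    def test_zero_events_in_an_arm_is_an_error(self):
        with pytest.raises(ValueError, match="non_initiation"):
            fit_outcome_model(one_stratum_panel(ev_b=0))

    def test_polynomial_time_form_close_to_dummies_on_flat_hazard(self):
        rng = np.random.default_rng(5)
        n = 6000
        t = rng.integers(0, 12, n)
        arm_ind = rng.integers(0, 2, n)
        p = 0.05 * np.where(arm_ind > 0, 0.7, 1.0)
        event = (rng.random(n) < p).astype(int)
        panel = panel_from_arrays(
            t, event, np.zeros(n, dtype=int),
            arm=np.where(arm_ind > 0, ARM_INITIATION, ARM_NON_INITIATION), person=np.arange(n),
        )
        panel["weight"] = 1.0
        d = fit_outcome_model(panel, "dummies")
        q = fit_outcome_model(panel, "poly2")
        assert d.irr == pytest.approx(q.irr, rel=0.02)


class TestRates:
    def test_rate_example_five_events_per_hundred_person_months(self):
        n = 100
        event = np.zeros(n, dtype=int)
        event[:5] = 1
        panel = panel_from_arrays(np.zeros(n, dtype=int), event, np.zeros(n, dtype=int),
                                  arm=[ARM_INITIATION] * n, person=np.arange(n))
        panel["weight"] = 1.0
        assert weighted_incidence_rate(panel, ARM_INITIATION) == pytest.approx(600.0)

    def test_no_events_rate_zero_and_weight_scale_invariance(self):
        n = 60
        panel = panel_from_arrays(np.zeros(n, dtype=int), np.zeros(n, dtype=int), np.zeros(n, dtype=int),
                                  arm=[ARM_INITIATION] * n, person=np.arange(n))
        panel["weight"] = 1.0
        assert weighted_incidence_rate(panel, ARM_INITIATION) == 0.0
        panel["event"] = (np.arange(n) < 6).astype(int)
        r1 = weighted_incidence_rate(panel, ARM_INITIATION)
        panel["weight"] = 3.0
        assert weighted_incidence_rate(panel, ARM_INITIATION) == pytest.approx(r1)

    def test_zero_person_time_is_an_error(self):
        panel = panel_from_arrays(np.zeros(1, dtype=int), np.zeros(1, dtype=int), np.zeros(1, dtype=int),
                                  arm=[ARM_INITIATION], person=[1], py=[0.0])
        panel["weight"] = 1.0
        with pytest.raises(ZeroDivisionError):
            weighted_incidence_rate(panel, ARM_INITIATION)


class TestCumulativeIncidence:
    def test_constant_hazard_closed_form(self):
        # 1000 clones, deterministic 1% hazard realised as exact fractions
        rows = []
        at_risk = 1000.0
        for t in range(24):
            rows.append((t, at_risk * 0.01, at_risk))
            at_risk *= 0.99
        t_arr = np.concatenate([[t] * 2 for t, _, _ in rows])
        ev = np.concatenate([[1, 0] for _ in rows])
        w = np.concatenate([[e, n - e] for _, e, n in rows])
        panel = panel_from_arrays(t_arr.astype(int), ev.astype(int), np.zeros(t_arr.size, dtype=int),
                                  arm=[ARM_INITIATION] * t_arr.size, person=np.arange(t_arr.size))
        panel["weight"] = w
        curve = cumulative_incidence_curve(panel, ARM_INITIATION)
        assert curve["cumulative_incidence"].iloc[23] == pytest.approx(1 - 0.99**24, abs=1e-12)
        assert (np.diff(curve["cumulative_incidence"]) >= -1e-15).all()
        assert curve["cumulative_incidence"].between(0, 1).all()

    def test_degenerate_curves(self):
        n = 10
        panel = panel_from_arrays(np.arange(n), np.zeros(n, dtype=int), np.zeros(n, dtype=int),
                                  arm=[ARM_INITIATION] * n, person=np.zeros(n, dtype=int))
        panel["weight"] = 1.0
        curve = cumulative_incidence_curve(panel, ARM_INITIATION)
        assert (curve["cumulative_incidence"] == 0).all()

    def test_recurrent_panel_rejected(self):
        panel = panel_from_arrays(np.array([0, 1]), np.array([1, 1]), np.zeros(2, dtype=int),
                                  arm=[ARM_INITIATION] * 2, person=np.array([5, 5]))
        panel["weight"] = 1.0
        with pytest.raises(ValueError, match="first-event"):
            cumulative_incidence_curve(panel, ARM_INITIATION)


class TestRecurrentPanel:
    def spec(self):
        return TrialSpec(outcome_type="x", recurrent=True)

    def persons(self):
        return pd.DataFrame(
            [{"person_id": 1, "age_at_index": 20.0, "index_date": pd.Timestamp("2012-01-01"),
              "death_date": pd.NaT, "emigration_date": pd.NaT}]
        )

    def test_two_events_full_person_time(self):
        start = pd.Timestamp("2012-01-01")
        ev = pd.DataFrame({"person_id": [1, 1], "date": [start + pd.Timedelta(days=75), start + pd.Timedelta(days=160)], "outcome_type": ["x", "x"]})
        panel = prepare_recurrent_panel(self.persons(), ev, self.spec())
        assert len(panel) == 24
        assert panel["event"].sum() == 2
        assert panel.loc[panel["t"] == 2, "event"].item() == 1
        assert panel.loc[panel["t"] == 5, "event"].item() == 1
        assert panel["person_years"].sum() == pytest.approx(2.0)

    def test_three_events_one_interval_count_once(self):
        start = pd.Timestamp("2012-01-01")
        ev = pd.DataFrame({"person_id": [1] * 3, "date": [start + pd.Timedelta(days=d) for d in (121, 125, 129)], "outcome_type": ["x"] * 3})
        panel = prepare_recurrent_panel(self.persons(), ev, self.spec())
        assert panel["event"].sum() == 1
        assert panel.loc[panel["t"] == 4, "event"].item() == 1

    def test_no_events_matches_first_event_rows(self):
        panel = prepare_recurrent_panel(self.persons(), pd.DataFrame(columns=["person_id", "date", "outcome_type"]), self.spec())
        assert len(panel) == 24 and panel["event"].sum() == 0

    def test_non_recurrent_spec_rejected(self):
        with pytest.raises(ValueError):
            prepare_recurrent_panel(self.persons(), pd.DataFrame(), TrialSpec(outcome_type="x", recurrent=False))
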