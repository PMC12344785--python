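"""Eligibility, follow-up windows, and expansion into the monthly panel.

Follow-up is partitioned into consecutive 30-day intervals from the index
date; intervals are half-open ``[30t, 30(t+1))`` in days since index, so an
event on a boundary day belongs to the later interval.  A full interval
contributes 1/12 person-year; a partial final interval contributes pro rata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_registry import DAYS_PER_INTERVAL, RegisterTables, _SCHEMAS

__all__ = [
    "EligibilitySpec",
    "FollowupWindow",
    "load_register_tables",
    "apply_eligibility",
    "build_followup_window",
    "expand_person_months",
]

ADHD_DRUG_CLASSES = {"stimulant", "non_stimulant"}


@dataclass(frozen=True)
class EligibilitySpec:
    """New-user eligibility: age range at index and a drug washout window."""

    age_min: float = 6.0
    age_max: float = 64.0
    washout_months: int = 18
    subcohort_age_min: float | None = None  # e.g. 15 for transport/criminality
    enrolment_start: str | None = None
    enrolment_end: str | None = None
    admin_end_date: str = "2020-12-31"

    def __post_init__(self):
        if self.age_min > self.age_max:
            raise ValueError("age_min must be <= age_max")
        if self.washout_months <= 0:
            raise ValueError("washout_months must be positive")

    @property
    def effective_age_min(self) -> float:
        return self.subcohort_age_min if self.subcohort_age_min is not None else self.age_min


@dataclass(frozen=True)
class FollowupWindow:
    person_id: int
    start: pd.Timestamp
    end: pd.Timestamp
    end_reason: str  # event | death | emigration | horizon | admin_end

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("follow-up window must satisfy start <= end")


def load_register_tables(in_dir) -> RegisterTables:
    """Read the four register CSVs, parsing ISO-8601 dates; schema-checked."""
    in_dir = Path(in_dir)
    frames = {}
    for name, cols in _SCHEMAS.items():
        path = in_dir / f"{name}.csv"
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name}.csv missing columns {missing}")
        for col in df.columns:
            if col.endswith("date") or col == "date":
                df[col] = pd.to_datetime(df[col], format="ISO8601")
        frames[name] = df
    return RegisterTables(**frames)


def apply_eligibility(
    persons: pd.DataFrame,
    dispensations: pd.DataFrame,
    spec: EligibilitySpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply eligibility criteria in a fixed order; return survivors + log.

    Order (each criterion applied to the survivors of the previous one):
    age at index in range -> incident diagnosis inside the enrolment window
    -> no ADHD-drug dispensation within the washout window before index.
    """
    if persons["index_date"].isna().any():
        raise ValueError("persons table has missing index_date")
    df = persons
    log_rows = [("assessed", len(df))]

    age = df["age_at_index"]
    amin = spec.effective_age_min
    keep = (age >= amin) & (age <= spec.age_max)
    log_rows.append(("age_out_of_range", int((~keep).sum())))
    df = df[keep]

    if spec.enrolment_start is not None or spec.enrolment_end is not None:
        lo = pd.Timestamp(spec.enrolment_start) if spec.enrolment_start else pd.Timestamp.min
        hi = pd.Timestamp(spec.enrolment_end) if spec.enrolment_end else pd.Timestamp.max
        keep = (df["index_date"] >= lo) & (df["index_date"] <= hi)
        log_rows.append(("outside_enrolment_window", int((~keep).sum())))
        df = df[keep]
    else:
        log_rows.append(("outside_enrolment_window", 0))

    washout_days = spec.washout_months * DAYS_PER_INTERVAL
    if len(dispensations):
        d = dispensations.merge(df[["person_id", "index_date"]], on="person_id", how="inner")
        delta = (d["date"] - d["index_date"]).dt.days
        prevalent_ids = set(d.loc[(delta < 0) & (delta >= -washout_days), "person_id"])
    else:
        prevalent_ids = set()
    keep = ~df["person_id"].isin(prevalent_ids)
    log_rows.append(("washout_violation", int((~keep).sum())))
    df = df[keep]
    log_rows.append(("eligible", len(df)))

    log = pd.DataFrame(log_rows, columns=["criterion", "n"])
    return df.reset_index(drop=True), log


def build_followup_window(
    person: pd.Series,
    events: pd.DataFrame,
    outcome_type: str,
    horizon_months: int,
    admin_end_date,
    stop_at_event: bool = True,
) -> FollowupWindow:
    """Earliest of event (optional), death, emigration, horizon, admin end."""
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    index_date = person["index_date"]
    candidates = {"horizon": index_date + pd.Timedelta(days=horizon_months * DAYS_PER_INTERVAL)}
    admin_end = pd.Timestamp(admin_end_date)
    candidates["admin_end"] = admin_end + pd.Timedelta(days=1)  # followed through admin end
    if pd.notna(person.get("death_date")):
        candidates["death"] = person["death_date"]
    if pd.notna(person.get("emigration_date")):
        candidates["emigration"] = person["emigration_date"]
    if stop_at_event and len(events):
        ev = events[
            (events["person_id"] == person["person_id"])
            & (events["outcome_type"] == outcome_type)
            & (events["date"] >= index_date)
        ]
        if len(ev):
            candidates["event"] = ev["date"].min()
    # ties resolved in favour of the event (conservative toward outcomes)
    order = ["event", "death", "emigration", "admin_end", "horizon"]
    reason = min(candidates, key=lambda k: (candidates[k], order.index(k)))
    return FollowupWindow(person_id=int(person["person_id"]), start=index_date, end=candidates[reason], end_reason=reason)


def expand_person_months(
    person: pd.Series,
    window: FollowupWindow,
    events: pd.DataFrame,
    covariate_history: pd.DataFrame | None = None,
    outcome_type: str | None = None,
    recurrent: bool = False,
) -> pd.DataFrame:
    """One row per 30-day interval inside the follow-up window.

    ``covariate_history`` is a long table (person_id, date, code) of dated
    time-varying covariate records; interval ``t`` carries the indicator of a
    record dated in interval ``t - 1`` (lag one month; the interval before
    the index date feeds ``t = 0``).  The event indicator is capped at one
    per interval.  The last, possibly partial, interval contributes
    person-time pro rata; an event interval contributes its full pro-rata
    share.
    """
    if window.end < window.start:
        raise ValueError("invalid follow-up window")
    index_date = window.start
    total_days = (window.end - index_date).days
    if window.end_reason == "event":
        total_days += 1  # the event day itself is inside follow-up
    n_rows = max(1, int(np.ceil(total_days / DAYS_PER_INTERVAL)))
    t = np.arange(n_rows)
    days_in = np.full(n_rows, DAYS_PER_INTERVAL, dtype=float)
    days_in[-1] = total_days - DAYS_PER_INTERVAL * (n_rows - 1)

    event = np.zeros(n_rows, dtype=int)
    event_day = np.full(n_rows, -1, dtype=int)  # earliest event day in the interval
    if len(events):
        ev = events[(events["person_id"] == person["person_id"]) & (events["date"] >= index_date)]
        if outcome_type is not None:
            ev = ev[ev["outcome_type"] == outcome_type]
        ev_days = np.sort((ev["date"] - index_date).dt.days.to_numpy())
        ev_t = ev_days // DAYS_PER_INTERVAL
        keep = (ev_t >= 0) & (ev_t < n_rows)
        ev_days, ev_t = ev_days[keep], ev_t[keep]
        if not recurrent and ev_t.size:
            ev_days, ev_t = ev_days[:1], ev_t[:1]
        for d_, t_ in zip(ev_days[::-1], ev_t[::-1]):
            event[t_] = 1
            event_day[t_] = d_

    out = pd.DataFrame(
        {
            "person_id": person["person_id"],
            "t": t,
            "event": event,
            "event_day": event_day,
            "person_years": days_in / DAYS_PER_INTERVAL / 12.0,
        }
    )
    if covariate_history is not None and len(covariate_history):
        hist = covariate_history[covariate_history["person_id"] == person["person_id"]]
        for code, grp in hist.groupby("code"):
            g_t = ((grp["date"] - index_date).dt.days // DAYS_PER_INTERVAL).to_numpy()
            out[f"{code}_lag1"] = np.isin(t - 1, g_t).astype(float)  # measured in t-1
    return out
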