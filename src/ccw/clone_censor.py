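"""Cloning, dispensation-based exposure timelines, and protocol censoring.

Each eligible person is duplicated into two clones at time zero: one assigned
to "initiate drug treatment within the grace period and remain on it", one to
"never initiate during follow-up".  A clone is artificially censored at the
first interval in which its observed data deviate from the assigned strategy;
the censoring indicator marks that first deviating interval so the censoring
mechanism can be modelled.

Exposure status is derived from dispensations by days-supply coverage: an
interval is treated when dispensed supply covers at least one of its days, or
when the uncovered gap since the last covered interval does not exceed
``max_gap_intervals`` (a refill-gap allowance; one interval by default, the
usual pharmacoepidemiology convention when the register does not record
treatment stops).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import EligibilitySpec
from .synthetic_registry import DAYS_PER_INTERVAL, DRUG_CLASSES

__all__ = [
    "TrialSpec",
    "ExposureTimeline",
    "Timelines",
    "compute_exposure_intervals",
    "compute_exposure_timelines",
    "censor_intervals",
    "make_clones",
    "apply_protocol_censoring",
    "ARM_INITIATION",
    "ARM_NON_INITIATION",
]

ARM_INITIATION = "initiation"
ARM_NON_INITIATION = "non_initiation"

UNTREATED, TREATED_INITIAL, TREATED_OTHER = 0, 1, 2


@dataclass(frozen=True)
class TrialSpec:
    """Declarative description of one emulated trial."""

    outcome_type: str
    grace_months: int = 3
    horizon_months: int = 24
    allow_switching: bool = False
    recurrent: bool = False
    comparison: str = "initiation_vs_none"  # or "stimulant_vs_nonstimulant"
    eligibility: EligibilitySpec = field(default_factory=EligibilitySpec)
    max_gap_intervals: int = 1
    supply_carryover: bool = True

    def __post_init__(self):
        if self.grace_months > self.horizon_months:
            raise ValueError("grace_months must be <= horizon_months")
        if self.comparison not in ("initiation_vs_none", "stimulant_vs_nonstimulant"):
            raise ValueError(f"unknown comparison {self.comparison!r}")


@dataclass
class ExposureTimeline:
    person_id: int
    status: np.ndarray              # per-interval code in {0, 1, 2}
    initiation_interval: int | None
    discontinuation_interval: int | None
    switch_interval: int | None


@dataclass
class Timelines:
    """Struct-of-arrays exposure timelines for a whole cohort (-1 = none)."""

    person_id: np.ndarray
    init: np.ndarray
    disc: np.ndarray
    switch: np.ndarray
    initial_class: np.ndarray  # index into DRUG_CLASSES, -1 if never treated


def _coverage_matrix(person_pos, day, supply, n, horizon, carryover):
    """Covered-interval boolean matrix from dispensation segments.

    Rows must be sorted by person and date.  With carryover, a refill made
    while supply remains is queued to start when the running supply ends.
    """
    day = day.astype(np.int64)
    supply = supply.astype(np.int64)
    if np.any(supply < 0):
        raise ValueError("days_supply must be non-negative")
    if carryover and len(day):
        start = np.empty_like(day)
        end = np.empty_like(day)
        # running coverage end within person: e_i = max(o_i, e_{i-1}) + s_i
        prev_p = -1
        e = 0
        for i in range(len(day)):
            p = person_pos[i]
            if p != prev_p:
                e = -(1 << 60)
                prev_p = p
            s0 = max(day[i], e)
            start[i] = s0
            e = s0 + supply[i]
            end[i] = e
    else:
        start = day
        end = day + supply
    start = np.maximum(start, 0)
    end = np.minimum(end, horizon * DAYS_PER_INTERVAL)
    keep = end > start
    cov = np.zeros((n, horizon + 1), dtype=np.int32)
    if keep.any():
        t0 = start[keep] // DAYS_PER_INTERVAL
        t1 = (end[keep] - 1) // DAYS_PER_INTERVAL
        np.add.at(cov, (person_pos[keep], t0), 1)
        np.add.at(cov, (person_pos[keep], t1 + 1), -1)
    return np.cumsum(cov, axis=1)[:, :horizon] > 0


def compute_exposure_timelines(
    dispensations: pd.DataFrame,
    persons: pd.DataFrame,
    horizon_months: int,
    supply_carryover: bool = True,
    max_gap_intervals: int = 1,
) -> Timelines:
    """Vectorized exposure reconstruction for every person in ``persons``."""
    n = len(persons)
    pid = persons["person_id"].to_numpy()
    init = np.full(n, -1)
    disc = np.full(n, -1)
    switch = np.full(n, -1)
    initial_class = np.full(n, -1)
    if not len(dispensations):
        return Timelines(pid, init, disc, switch, initial_class)

    d = dispensations.merge(persons[["person_id", "index_date"]], on="person_id", how="inner")
    d = d.sort_values(["person_id", "date"], kind="stable")
    pos_map = pd.Series(np.arange(n), index=pid)
    person_pos = pos_map[d["person_id"]].to_numpy()
    day = (d["date"] - d["index_date"]).dt.days.to_numpy()
    supply = d["days_supply"].to_numpy()
    if np.any(supply < 0):
        raise ValueError("negative days_supply")
    cls = d["drug_class"].map({c: i for i, c in enumerate(DRUG_CLASSES)}).to_numpy()
    if np.isnan(cls.astype(float)).any():
        raise ValueError("unknown drug_class in dispensations")

    H = horizon_months
    cov_by_class = [
        _coverage_matrix(person_pos[cls == k], day[cls == k], supply[cls == k], n, H, supply_carryover)
        for k in range(len(DRUG_CLASSES))
    ]
    covered = np.logical_or.reduce(cov_by_class)

    any_cov = covered.any(axis=1)
    init[any_cov] = covered[any_cov].argmax(axis=1)
    # class at initiation = class covering the initiation interval (ties:
    # listed class order, stimulant first)
    for k in range(len(DRUG_CLASSES)):
        sel = any_cov & (initial_class < 0) & cov_by_class[k][np.arange(n), np.maximum(init, 0)]
        initial_class[sel] = k

    t_idx = np.arange(H)
    last_cov = np.maximum.accumulate(np.where(covered, t_idx[None, :], -1), axis=1)
    gap_break = (last_cov >= 0) & ((t_idx[None, :] - last_cov) > max_gap_intervals)
    has_disc = gap_break.any(axis=1)
    disc[has_disc] = gap_break[has_disc].argmax(axis=1)

    # first interval covered by a class other than the one at initiation and
    # no longer covered by the initiation class
    other = np.zeros((n, H), dtype=bool)
    for k in range(len(DRUG_CLASSES)):
        rows = initial_class == k
        if rows.any():
            other_cov = np.logical_or.reduce([cov_by_class[j][rows] for j in range(len(DRUG_CLASSES)) if j != k]) \
                if len(DRUG_CLASSES) > 1 else np.zeros((rows.sum(), H), dtype=bool)
            other[rows] = other_cov & ~cov_by_class[k][rows]
    has_sw = other.any(axis=1)
    switch[has_sw] = other[has_sw].argmax(axis=1)
    return Timelines(pid, init, disc, switch, initial_class)


def compute_exposure_intervals(
    dispensations: pd.DataFrame,
    index_date,
    supply_carryover: bool = True,
    max_gap_intervals: int = 1,
    horizon_months: int = 24,
) -> ExposureTimeline:
    """Exposure timeline for a single person (dispensations sorted by date)."""
    pid = int(dispensations["person_id"].iloc[0]) if len(dispensations) else -1
    persons = pd.DataFrame({"person_id": [pid], "index_date": [pd.Timestamp(index_date)]})
    tl = compute_exposure_timelines(dispensations, persons, horizon_months, supply_carryover, max_gap_intervals)
    H = horizon_months
    status = np.zeros(H, dtype=int)
    i0, dd, sw = int(tl.init[0]), int(tl.disc[0]), int(tl.switch[0])
    if i0 >= 0:
        end = dd if dd >= 0 else H
        status[i0:end] = TREATED_INITIAL
        if sw >= 0:
            status[sw:end] = TREATED_OTHER
    return ExposureTimeline(
        person_id=pid,
        status=status,
        initiation_interval=None if i0 < 0 else i0,
        discontinuation_interval=None if dd < 0 else dd,
        switch_interval=None if sw < 0 else sw,
    )


def censor_intervals(timelines: Timelines, spec: TrialSpec) -> tuple[np.ndarray, np.ndarray]:
    """Artificial-censoring interval per clone arm (a large value = never).

    Initiation arm: censored at the end of the grace period when treatment
    was never started within it; at definitive discontinuation whenever it
    occurs (stopping treatment is a deviation from "remain on therapy" even
    inside the grace window); and, unless switching is allowed, at a
    post-grace class switch (switching inside grace, while still treated,
    is not a deviation).  Non-initiation arm: censored at the first receipt
    of any ADHD drug.
    """
    NEVER = 1 << 30
    g = spec.grace_months
    init, disc, sw = timelines.init, timelines.disc, timelines.switch
    started = (init >= 0) & (init < g)

    c1 = np.full(init.shape, NEVER, dtype=np.int64)
    c1[~started] = g
    disc_c = np.where(disc >= 0, disc, NEVER)
    c1 = np.where(started, disc_c, c1)
    if not spec.allow_switching:
        sw_c = np.where(sw >= g, sw, NEVER)
        c1 = np.where(started, np.minimum(c1, sw_c), c1)

    c0 = np.where(init >= 0, init, NEVER).astype(np.int64)
    return c1, c0


def make_clones(panel: pd.DataFrame, spec: TrialSpec) -> pd.DataFrame:
    """Duplicate every person's rows into the two strategy arms."""
    if "clone_arm" in panel.columns:
        raise ValueError("panel already contains clones")
    a = panel.copy()
    b = panel.copy()
    a["clone_arm"] = ARM_INITIATION
    b["clone_arm"] = ARM_NON_INITIATION
    out = pd.concat([a, b], ignore_index=True)
    return out.sort_values(["person_id", "clone_arm", "t"], kind="stable").reset_index(drop=True)


def apply_protocol_censoring(
    cloned_panel: pd.DataFrame,
    timelines: Timelines,
    spec: TrialSpec,
) -> pd.DataFrame:
    """Drop rows after each clone's censoring interval and flag the first one.

    An event in the first deviating interval is kept (and the clone censored
    from the next interval) when its date is on or before the deviation
    date, taken as the first day of the deviating interval; this implements
    the tie rule that an event coinciding with the deviation counts.
    """
    if "clone_arm" not in cloned_panel.columns:
        raise ValueError("panel has no clones; call make_clones first")
    c1, c0 = censor_intervals(timelines, spec)
    cmap = pd.DataFrame({"person_id": timelines.person_id, ARM_INITIATION: c1, ARM_NON_INITIATION: c0})
    long = cmap.melt(id_vars="person_id", var_name="clone_arm", value_name="censor_interval")
    out = cloned_panel.merge(long, on=["person_id", "clone_arm"], how="left", validate="many_to_one")
    if out["censor_interval"].isna().any():
        raise ValueError("panel contains persons absent from the exposure timelines")

    # tie rule: qualifying event in the deviating interval defers censoring
    if "event_day" in out.columns:
        qualifies = (
            (out["t"] == out["censor_interval"])
            & (out["event"] > 0)
            & (out["event_day"] <= out["censor_interval"] * DAYS_PER_INTERVAL)
        )
        out.loc[qualifies, "censor_interval"] += 1

    out = out[out["t"] <= out["censor_interval"]].copy()
    out["censored"] = (out["t"] == out["censor_interval"]).astype(int)
    # the censored interval itself contributes no outcome information
    out.loc[out["censored"] == 1, ["event", "person_years"]] = 0
    return out.reset_index(drop=True)
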