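"""Array-level clone-censor-weight pipeline.

The DataFrame operations in :mod:`ccw.cohort`, :mod:`ccw.clone_censor`,
:mod:`ccw.ipcw` and :mod:`ccw.estimation` define the semantics row by row;
this module implements the same pipeline on flat numpy arrays so that a full
re-estimate (cloning, censoring, weight fitting, outcome fitting) costs tens
of milliseconds and person-level bootstrap with full refitting is practical.
A property test asserts the two routes build identical panels.

Usage: build a :class:`TrialData` once from the register tables, then call
:func:`estimate_on_index` with any index vector of persons -- the identity
permutation for the point estimate, a with-replacement draw for a bootstrap
resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clone_censor import (
    ARM_INITIATION,
    ARM_NON_INITIATION,
    TrialSpec,
    censor_intervals,
    compute_exposure_timelines,
)
from .cohort import apply_eligibility
from .estimation import EstimateResult
from .ipcw import CensoringModelSpec, _fit_censoring_arrays
from .synthetic_registry import DAYS_PER_INTERVAL, TV_CODE, RegisterTables
from ._glm import fit_pooled_logit

__all__ = ["TrialData", "estimate_on_index", "run_ccw_estimate", "naive_initiator_irr"]

NEVER = np.int64(1) << 30

# covariates derivable from the persons table demographics
_DEMOGRAPHIC_COVARIATES = ("female", "age_z", "edu_upper_secondary", "edu_post_secondary")


@dataclass
class TrialData:
    """Precomputed per-person arrays for one emulated trial."""

    person_id: np.ndarray
    X: np.ndarray                 # (n, p) baseline covariates
    cov_names: tuple
    Llag: np.ndarray              # (n, H) lag-1 time-varying confounder
    event_day: np.ndarray         # (n, H) first event day per interval, -1 none
    first_event_day: np.ndarray   # (n,) float, inf if none
    end_day_base: np.ndarray      # (n,) follow-up end ignoring events
    c_init: np.ndarray            # (n,) censor interval, initiation-arm clone
    c_non: np.ndarray             # (n,) censor interval, non-initiation-arm clone
    fixed_arm: np.ndarray | None  # head-to-head: per-person arm; None otherwise
    spec: TrialSpec
    exclusion_log: pd.DataFrame
    horizon: int

    @property
    def n(self) -> int:
        return self.person_id.size

    @classmethod
    def from_tables(
        cls,
        tables: RegisterTables,
        spec: TrialSpec,
        covariates: tuple[str, ...],
    ) -> "TrialData":
        persons, diagnoses, dispensations, events = tables
        elig, log = apply_eligibility(persons, dispensations, spec.eligibility)
        n = len(elig)
        H = spec.horizon_months
        pid = elig["person_id"].to_numpy()
        index_date = elig["index_date"]

        # covariate matrix: demographics derived from the persons table plus
        # any named baseline covariate column
        cols = {}
        cols["female"] = (elig["sex"] == "F").to_numpy(float)
        cols["age_z"] = ((elig["age_at_index"] - 18.0) / 10.0).to_numpy(float)
        cols["edu_upper_secondary"] = (elig["education_level"] == "upper_secondary").to_numpy(float)
        cols["edu_post_secondary"] = (elig["education_level"] == "post_secondary").to_numpy(float)
        X_cols = []
        names = []
        for name in covariates:
            if name == TV_CODE:
                continue
            if name in cols:
                X_cols.append(cols[name])
            elif name in elig.columns:
                X_cols.append(elig[name].to_numpy(float))
            else:
                raise ValueError(f"covariate {name!r} not found in persons table")
            names.append(name)
        X = np.column_stack(X_cols) if X_cols else np.empty((n, 0))

        pos = pd.Series(np.arange(n), index=pid)

        # lag-1 time-varying confounder from dated diagnosis records: the
        # indicator at interval t is a record dated in interval t-1
        Llag = np.zeros((n, H))
        dg = diagnoses[diagnoses["code"] == TV_CODE].merge(
            elig[["person_id", "index_date"]], on="person_id", how="inner"
        )
        if len(dg):
            day = (dg["date"] - dg["index_date"]).dt.days.to_numpy()
            t_rec = np.floor_divide(day, DAYS_PER_INTERVAL) + 1  # known one interval later
            ok = (t_rec >= 0) & (t_rec < H)
            Llag[pos[dg["person_id"]].to_numpy()[ok], t_rec[ok]] = 1.0

        ev = events[events["outcome_type"] == spec.outcome_type].merge(
            elig[["person_id", "index_date"]], on="person_id", how="inner"
        )
        event_day = np.full((n, H), -1, dtype=np.int64)
        if len(ev):
            day = (ev["date"] - ev["index_date"]).dt.days.to_numpy()
            t_ev = day // DAYS_PER_INTERVAL
            ok = (day >= 0) & (t_ev < H)
            pp, dd = pos[ev["person_id"]].to_numpy()[ok], day[ok]
            order = np.argsort(dd)[::-1]  # earliest event in an interval wins
            event_day[pp[order], dd[order] // DAYS_PER_INTERVAL] = dd[order]
        has_ev = (event_day >= 0).any(axis=1)
        first_event_day = np.full(n, np.inf)
        if has_ev.any():
            masked = np.where(event_day >= 0, event_day, np.iinfo(np.int64).max)
            first_event_day[has_ev] = masked[has_ev].min(axis=1)

        death_day = (elig["death_date"] - index_date).dt.days.to_numpy(float)
        emig_day = (elig["emigration_date"] - index_date).dt.days.to_numpy(float)
        death_day[np.isnan(death_day)] = np.inf
        emig_day[np.isnan(emig_day)] = np.inf
        admin_day = (pd.Timestamp(spec.eligibility.admin_end_date) - index_date).dt.days.to_numpy(float) + 1
        end_day_base = np.minimum.reduce([death_day, emig_day, admin_day, np.full(n, H * DAYS_PER_INTERVAL, float)])
        end_day_base = np.maximum(end_day_base, 0.0)

        timelines = compute_exposure_timelines(
            dispensations, elig, H, spec.supply_carryover, spec.max_gap_intervals
        )

        fixed_arm = None
        if spec.comparison == "stimulant_vs_nonstimulant":
            # re-base time zero to the initiation date; keep initiators only
            keep = timelines.init >= 0
            shift = timelines.init[keep] * DAYS_PER_INTERVAL
            sel = np.where(keep)[0]
            fixed_arm = (timelines.initial_class[keep] == 0).astype(np.int64)  # stimulant = arm 1
            ed = np.full((sel.size, H), -1, dtype=np.int64)
            Ll = np.zeros((sel.size, H))
            for j, (i, s) in enumerate(zip(sel, timelines.init[keep])):
                m = H - s
                ev_row = event_day[i, s:]
                ed[j, :m] = np.where(ev_row >= 0, ev_row - s * DAYS_PER_INTERVAL, -1)
                Ll[j, :m] = Llag[i, s:]
            event_day, Llag, X = ed, Ll, X[sel]
            fe = np.full(sel.size, np.inf)
            rows_has = (ed >= 0).any(axis=1)
            masked = np.where(ed >= 0, ed, np.iinfo(np.int64).max)
            fe[rows_has] = masked[rows_has].min(axis=1)
            first_event_day = fe
            end_day_base = np.minimum(end_day_base[sel] - shift, (H - timelines.init[keep]) * DAYS_PER_INTERVAL)
            dv = np.where(timelines.disc[keep] >= 0, timelines.disc[keep] - timelines.init[keep], NEVER)
            if not spec.allow_switching:
                swv = np.where(timelines.switch[keep] >= 0, timelines.switch[keep] - timelines.init[keep], NEVER)
                dv = np.minimum(dv, swv)
            c_init = c_non = dv.astype(np.int64)
            pid = pid[sel]
        else:
            c_init, c_non = censor_intervals(timelines, spec)

        return cls(
            person_id=pid,
            X=X,
            cov_names=tuple(names),
            Llag=Llag,
            event_day=event_day,
            first_event_day=first_event_day,
            end_day_base=end_day_base,
            c_init=c_init.astype(np.int64),
            c_non=c_non.astype(np.int64),
            fixed_arm=fixed_arm,
            spec=spec,
            exclusion_log=log,
            horizon=H,
        )


def _arm_rows(data: TrialData, idx: np.ndarray, arm: int):
    """Row arrays (t, event, person-time, censor flag, row->person map) for one arm."""
    H = data.horizon
    C = (data.c_init if arm == 1 else data.c_non)[idx].copy()
    end_day = data.end_day_base[idx].copy()
    if not data.spec.recurrent:
        end_day = np.minimum(end_day, data.first_event_day[idx] + 1)
    if data.fixed_arm is not None:
        # head-to-head: a person belongs to exactly one arm
        C = np.where(data.fixed_arm[idx] == arm, C, -1)
        C[data.fixed_arm[idx] != arm] = -1

    rows_nat = np.ceil(end_day / DAYS_PER_INTERVAL).astype(np.int64)
    rows_nat = np.clip(rows_nat, 0, H)
    if data.fixed_arm is not None:
        rows_nat[data.fixed_arm[idx] != arm] = 0
        C[C < 0] = NEVER

    # tie rule: an event dated on the first day of the deviating interval is
    # counted and censoring deferred by one interval
    inb = C < H
    if inb.any():
        ev_at_c = np.full(C.shape, -1, dtype=np.int64)
        ev_at_c[inb] = data.event_day[idx[inb], C[inb]]
        defer = inb & (C < rows_nat) & (ev_at_c == C * DAYS_PER_INTERVAL)
        C[defer] += 1

    n_rows = np.minimum(rows_nat, C + 1)
    has_cens = C < rows_nat

    total = int(n_rows.sum())
    rep = np.repeat(np.arange(idx.size), n_rows)
    starts = np.concatenate([[0], np.cumsum(n_rows)[:-1]])
    t = np.arange(total) - np.repeat(starts, n_rows)

    cens = has_cens[rep] & (t == C[rep])
    event = (data.event_day[idx[rep], t] >= 0) & ~cens
    py = np.full(total, 1.0 / 12.0)
    last_nat = t == (rows_nat[rep] - 1)
    py[last_nat] = (end_day[rep][last_nat] - DAYS_PER_INTERVAL * (rows_nat[rep][last_nat] - 1)) / DAYS_PER_INTERVAL / 12.0
    py[cens] = 0.0
    return t, event.astype(float), py, cens, rep, n_rows


def _clone_cumprod(logp: np.ndarray, n_rows: np.ndarray) -> np.ndarray:
    cs = np.cumsum(logp)
    starts = np.concatenate([[0], np.cumsum(n_rows)[:-1]])
    starts = starts[n_rows > 0]
    base = cs[starts] - logp[starts]
    return cs - np.repeat(base, n_rows[n_rows > 0])


def estimate_on_index(
    data: TrialData,
    idx: np.ndarray,
    cens_spec: CensoringModelSpec,
    use_weights: bool = True,
    balance_at: int | None = None,
    with_panel: bool = False,
    warm_cache: dict | None = None,
):
    """Full clone-censor-weight estimate for the persons indexed by ``idx``.

    Duplicated indices (bootstrap resamples) are treated as distinct
    individuals.  Returns an :class:`EstimateResult`; with ``balance_at``
    set, standardized mean differences at that interval are attached to the
    diagnostics, and with ``with_panel=True`` the assembled person-interval
    panel is attached as a DataFrame.  ``warm_cache`` (a mutable dict owned
    by the caller) carries Newton warm starts between repeated calls, e.g.
    across bootstrap resamples.
    """
    idx = np.asarray(idx)
    arms = {}
    cache = warm_cache if warm_cache is not None else {}
    tv_in_model = TV_CODE in cens_spec.covariates
    for arm in (1, 0):
        t, y_ev, py, cens, rep, n_rows = _arm_rows(data, idx, arm)
        Xrow = data.X[idx[rep]]
        if tv_in_model:
            Xrow = np.column_stack([Xrow, data.Llag[idx[rep], t]])
        if use_weights:
            split = (
                cens_spec.separate_grace_model
                and arm == 1
                and data.fixed_arm is None
            )
            if split:
                # within-grace discontinuation, grace-end "never started",
                # and post-grace deviation are different censoring
                # mechanisms; model each window separately.  The grace-end
                # model additionally conditions on the confounder history
                # over the whole grace window: not having started by the
                # grace boundary depends on every monthly state that fed an
                # initiation decision, and omitting the earlier lags leaves
                # residual selection
                g = data.spec.grace_months
                p_cens = np.zeros(t.size)
                ok = True
                for tag, m in (("i", t < g), ("g", t == g), ("p", t > g)):
                    if m.any():
                        Xm = Xrow[m]
                        if tag == "g" and tv_in_model:
                            hist = data.Llag[idx[rep[m]], : min(g, data.horizon)]
                            Xm = np.column_stack([Xm, hist])
                        p_m, ok_m, f_m = _fit_censoring_arrays(
                            t[m], Xm, cens[m].astype(float), cens_spec.time_form,
                            start=cache.get(("cens", arm, tag)),
                        )
                        p_cens[m] = p_m
                        ok &= ok_m
                        if f_m is not None:
                            cache[("cens", arm, tag)] = f_m
            else:
                p_cens, ok, fit_c = _fit_censoring_arrays(
                    t, Xrow, cens.astype(float), cens_spec.time_form, start=cache.get(("cens", arm))
                )
                if fit_c is not None:
                    cache[("cens", arm)] = fit_c
            p_unc = 1.0 - p_cens
            bad = (~cens) & (p_unc <= 0)
            if bad.any():
                raise FloatingPointError("zero fitted probability of remaining uncensored")
            logp = np.where(cens, 0.0, -np.log(np.maximum(p_unc, 1e-300)))
            w = np.exp(_clone_cumprod(logp, n_rows))
            if cens_spec.stabilized:
                p_cens_m, _, fit_m = _fit_censoring_arrays(
                    t, None, cens.astype(float), cens_spec.time_form, start=cache.get(("marg", arm))
                )
                if fit_m is not None:
                    cache[("marg", arm)] = fit_m
                logp_m = np.where(cens, 0.0, np.log(np.maximum(1.0 - p_cens_m, 1e-300)))
                w = w * np.exp(_clone_cumprod(logp_m, n_rows))
            w_unc = w[~cens]
            if w_unc.size and cens_spec.truncation_percentile < 100.0:
                thr = np.percentile(w_unc, cens_spec.truncation_percentile)
                w = np.minimum(w, thr)
        else:
            w = np.ones(t.size)
        arms[arm] = (t, y_ev, py, cens, rep, w, Xrow)

    # outcome model on uncensored rows of both arms
    t_all = np.concatenate([arms[1][0][~arms[1][3]], arms[0][0][~arms[0][3]]])
    y_all = np.concatenate([arms[1][1][~arms[1][3]], arms[0][1][~arms[0][3]]])
    w_all = np.concatenate([arms[1][5][~arms[1][3]], arms[0][5][~arms[0][3]]])
    a_all = np.concatenate(
        [np.ones(int((~arms[1][3]).sum())), np.zeros(int((~arms[0][3]).sum()))]
    )
    for a, name in ((1.0, ARM_INITIATION), (0.0, ARM_NON_INITIATION)):
        if y_all[a_all == a].sum() == 0:
            raise ValueError(f"no events in arm {name!r}; the rate ratio is not estimable")
    ev_t = np.unique(t_all[y_all > 0])
    keep = np.isin(t_all, ev_t)
    fit = fit_pooled_logit(t_all[keep], a_all[keep, None], y_all[keep], w_all[keep], start=cache.get("outcome"))
    cache["outcome"] = fit
    if not fit.converged:
        raise RuntimeError("outcome model did not converge")
    beta = float(fit.beta[0])

    res = EstimateResult(
        irr=float(np.exp(beta)),
        log_irr=beta,
        model_meta={"time_form": "dummies", "n_rows": int(t_all.size), "converged": True},
        person_ids=frozenset(data.person_id[np.unique(idx)].tolist()),
    )
    se_parts = 0.0
    for arm, name in ((1, ARM_INITIATION), (0, ARM_NON_INITIATION)):
        t, y_ev, py, cens, rep, w, _ = arms[arm]
        m = ~cens
        ev = float(np.sum(w[m] * y_ev[m]))
        pyr = float(np.sum(w[m] * py[m]))
        res.weighted_events[name] = ev
        res.weighted_person_years[name] = pyr
        res.weighted_rate_per_1000py[name] = 1000.0 * ev / pyr if pyr > 0 else float("nan")
        if ev > 0:
            se_parts += float(np.sum((w[m] * y_ev[m]) ** 2)) / ev**2
    # weighted Poisson-type approximation to the sampling SE of log IRR;
    # used as the Monte-Carlo error scale for simulation checks
    res.diagnostics["approx_se_log_irr"] = float(np.sqrt(se_parts))

    if balance_at is not None:
        from .diagnostics import standardized_mean_difference

        rows = {}
        for arm in (1, 0):
            t, y_ev, py, cens, rep, w, Xrow = arms[arm]
            m = (t == balance_at) & ~cens
            if not m.any():
                raise ValueError(f"no at-risk rows at interval {balance_at}")
            rows[arm] = (Xrow[m], w[m])
        names = list(data.cov_names) + ([TV_CODE] if tv_in_model else [])
        bal = []
        for j, nm in enumerate(names):
            a, wa = rows[1][0][:, j], rows[1][1]
            b, wb = rows[0][0][:, j], rows[0][1]
            smd_u = standardized_mean_difference(a, b)
            smd_w = standardized_mean_difference(a, b, wa, wb)
            bal.append({"covariate": nm, "smd_unweighted": smd_u, "smd_weighted": smd_w,
                        "flag_unweighted": abs(smd_u) >= 0.10, "flag_weighted": abs(smd_w) >= 0.10})
        res.diagnostics["balance"] = bal

    if with_panel:
        frames = []
        for arm, name in ((1, ARM_INITIATION), (0, ARM_NON_INITIATION)):
            t, y_ev, py, cens, rep, w, Xrow = arms[arm]
            df = pd.DataFrame(
                {
                    "person_id": data.person_id[idx[rep]],
                    "clone_arm": name,
                    "t": t,
                    "event": y_ev.astype(int),
                    "person_years": py,
                    "censored": cens.astype(int),
                    "weight": np.where(cens, np.nan, w),
                }
            )
            for j, nm in enumerate(list(data.cov_names) + ([TV_CODE] if tv_in_model else [])):
                df[nm] = Xrow[:, j]
            frames.append(df)
        res.diagnostics["_panel"] = pd.concat(frames, ignore_index=True)
    return res


def run_ccw_estimate(
    tables: RegisterTables,
    spec: TrialSpec,
    cens_spec: CensoringModelSpec,
    use_weights: bool = True,
    balance_at: int | None = None,
    with_panel: bool = False,
) -> EstimateResult:
    """Point estimate of the per-protocol IRR from register tables."""
    data = TrialData.from_tables(tables, spec, cens_spec.covariates)
    return estimate_on_index(
        data, np.arange(data.n), cens_spec,
        use_weights=use_weights, balance_at=balance_at, with_panel=with_panel,
    )


def naive_initiator_irr(data: TrialData) -> float:
    """Biased ever-initiator versus never comparison, for demonstration.

    Classifies each person by whether initiation was *observed during their
    follow-up* (the classification a naive analysis would make from the
    dispensation record), counts all person-time from diagnosis in the
    classified group, and fits the unweighted pooled logistic model.  The
    pre-initiation waiting time is thereby misclassified as exposed --
    immortal time -- which biases the comparison even under a null effect.
    """
    idx = np.arange(data.n)
    end_day = np.minimum(data.end_day_base, data.first_event_day + 1)
    init_day = np.where(data.c_non < NEVER, data.c_non * DAYS_PER_INTERVAL, np.inf)
    grace = data.spec.grace_months
    group = (data.c_non < grace) & (init_day < end_day)

    rows_nat = np.clip(np.ceil(end_day / DAYS_PER_INTERVAL).astype(np.int64), 0, data.horizon)
    rep = np.repeat(idx, rows_nat)
    starts = np.concatenate([[0], np.cumsum(rows_nat)[:-1]])
    t = np.arange(int(rows_nat.sum())) - np.repeat(starts, rows_nat)
    y = (data.event_day[rep, t] >= 0).astype(float)
    g = group[rep].astype(float)
    ev_t = np.unique(t[y > 0])
    keep = np.isin(t, ev_t)
    fit = fit_pooled_logit(t[keep], g[keep, None], y[keep])
    return float(np.exp(fit.beta[0]))
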