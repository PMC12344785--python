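"""Synthetic pseudo-register generator with a known data-generating process.

The generator emulates the structure of national health registers as seen by a
pharmacoepidemiologist: a persons table (demographics, index diagnosis date,
death/emigration), dated drug dispensations with days supply, dated outcome
events by type, and dated diagnosis records carrying a time-varying
confounder.  Individual months are 30-day intervals counted from each
person's index (diagnosis) date.

The monthly data-generating process, per person:

* a binary time-varying confounder ``L`` with first-order dynamics -- its
  probability depends on last month's value and on last month's treatment
  status -- which raises both the discontinuation hazard and the outcome
  hazards.  This is the minimal structure under which unweighted per-protocol
  contrasts are biased while inverse-probability-of-censoring weighting is
  consistent;
* treatment initiation during the grace period, with log-odds depending on
  baseline covariates and lagged ``L`` (confounded initiation);
* absorbing discontinuation and class switching after initiation;
* per-outcome monthly Bernoulli events whose log-odds include covariate
  terms, lagged ``L``, and ``true_log_irr`` times current treatment;
* a small common hazard of death/emigration.

Randomness is laid out as one fixed-size uniform block per person (rows of a
single row-major draw), so enlarging ``n_individuals`` appends new people
without perturbing the draws of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "HazardModel",
    "TvConfounderModel",
    "SimulationConfig",
    "RegisterTables",
    "GroundTruth",
    "TruthResult",
    "simulate_cohort",
    "simulate_counterfactual_truth",
    "write_register_tables",
    "DAYS_PER_INTERVAL",
]

DAYS_PER_INTERVAL = 30
DRUG_CLASSES = ("stimulant", "non_stimulant")
TV_CODE = "tv_confounder"


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: name, distribution family, parameters."""

    name: str
    family: str  # bernoulli | normal | lognormal | poisson
    params: dict

    def draw(self, u: np.ndarray) -> np.ndarray:
        from scipy import stats

        u = np.clip(u, 1e-12, 1 - 1e-12)
        if self.family == "bernoulli":
            return (u < self.params["p"]).astype(float)
        if self.family == "normal":
            return self.params.get("mu", 0.0) + self.params.get("sigma", 1.0) * stats.norm.ppf(u)
        if self.family == "lognormal":
            return np.exp(self.params.get("mu", 0.0) + self.params.get("sigma", 1.0) * stats.norm.ppf(u))
        if self.family == "poisson":
            return stats.poisson.ppf(u, self.params["lam"])
        raise ValueError(f"unknown covariate family {self.family!r}")


@dataclass(frozen=True)
class HazardModel:
    """Monthly Bernoulli (log-odds) model: intercept + covariate terms.

    ``effects`` keys refer to baseline covariate names, the derived
    demographics (``female``, ``age_z``, ``edu_upper_secondary``,
    ``edu_post_secondary``) or the lagged confounder ``tv_confounder``.
    ``true_log_irr`` is the sustained-treatment effect; only outcome models
    use it.
    """

    intercept: float
    effects: dict = field(default_factory=dict)
    true_log_irr: float = 0.0


@dataclass(frozen=True)
class TvConfounderModel:
    """First-order dynamics of the binary time-varying confounder."""

    intercept: float = -2.3
    persistence: float = 2.0
    treatment_effect: float = -0.7
    effects: dict = field(default_factory=lambda: {"psych_comorbidity": 0.8})


def _default_covariates() -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec("psych_comorbidity", "bernoulli", {"p": 0.25}),
        CovariateSpec("prior_event", "bernoulli", {"p": 0.21}),
        CovariateSpec("comed_psychotropic", "bernoulli", {"p": 0.40}),
        CovariateSpec("hc_visits", "poisson", {"lam": 2.0}),
    )


def _default_outcomes() -> dict:
    # monthly baseline log-odds chosen so weighted rates land in the range the
    # study populations show (tens of events per 1000 person-years)
    return {
        "suicidal_behaviour": HazardModel(-6.64, {"psych_comorbidity": 0.7, "prior_event": 0.9, "tv_confounder": 0.9}, math.log(0.83)),
        "substance_misuse": HazardModel(
            -5.11,
            {"psych_comorbidity": 0.5, "prior_event": 0.8, "comed_psychotropic": 0.2, "hc_visits": 0.05, "age_z": 0.15, "tv_confounder": 0.8},
            math.log(0.85),
        ),
        "accidental_injury": HazardModel(-4.88, {"prior_event": 0.5, "tv_confounder": 0.4}, math.log(0.98)),
        "transport_accident": HazardModel(-6.10, {"age_z": 0.2, "prior_event": 0.5, "tv_confounder": 0.3}, math.log(0.88)),
        "criminality": HazardModel(-5.03, {"psych_comorbidity": 0.4, "prior_event": 1.0, "age_z": 0.1, "tv_confounder": 0.6}, math.log(0.87)),
        # negative-control outcome: independent of treatment and of all
        # modelled confounders by construction
        "type1_diabetes": HazardModel(-6.50, {}, 0.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int
    seed: int
    horizon_months: int = 24
    grace_months: int = 3
    baseline_covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    initiation_model: HazardModel = field(
        # intercept set so that, after averaging the covariate effects, about
        # 57% of the cohort initiates within a three-interval grace period
        default_factory=lambda: HazardModel(
            -0.78,
            {"psych_comorbidity": -0.5, "prior_event": -0.3, "comed_psychotropic": -0.2, "age_z": -0.1, "tv_confounder": -0.4},
        )
    )
    discontinuation_model: HazardModel = field(
        default_factory=lambda: HazardModel(-2.75, {"psych_comorbidity": 0.3, "age_z": -0.05, "tv_confounder": 1.2})
    )
    switch_prob: float = 0.008
    outcome_models: dict = field(default_factory=_default_outcomes)
    tv_confounder_model: TvConfounderModel = field(default_factory=TvConfounderModel)
    death_emigration_hazard: float = 0.0008
    recurrent: bool = True
    prevalent_user_frac: float = 0.04
    nonstimulant_frac: float = 0.12
    enrolment_start: str = "2007-01-01"
    enrolment_end: str = "2018-12-31"
    washout_check_window_months: int = 24

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.horizon_months <= 0 or self.grace_months <= 0:
            raise ValueError("horizon_months and grace_months must be positive")
        if self.horizon_months < self.grace_months:
            raise ValueError("horizon_months must be >= grace_months")
        for p, name in [
            (self.switch_prob, "switch_prob"),
            (self.death_emigration_hazard, "death_emigration_hazard"),
            (self.prevalent_user_frac, "prevalent_user_frac"),
            (self.nonstimulant_frac, "nonstimulant_frac"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not self.outcome_models:
            raise ValueError("at least one outcome model is required")

    def with_outcome(self, name: str, model: HazardModel) -> "SimulationConfig":
        out = dict(self.outcome_models)
        out[name] = model
        return replace(self, outcome_models=out)


class RegisterTables(NamedTuple):
    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    dispensations: pd.DataFrame
    events: pd.DataFrame


@dataclass
class GroundTruth:
    """Latent simulator state, exposed for tests and oracle checks."""

    covariates: pd.DataFrame       # derived covariate matrix incl. demographics
    L: np.ndarray                  # (n, H+1); L[:, t] is the value known at interval t
    init_interval: np.ndarray      # -1 if never initiated
    disc_interval: np.ndarray      # -1 if never discontinued
    switch_interval: np.ndarray    # -1 if never switched
    death_day: np.ndarray          # np.inf if none
    emigration_day: np.ndarray
    event_day: dict                # outcome -> (n, H) int day-in-followup, -1 none


class TruthResult(NamedTuple):
    irr: float
    mc_se: float
    rate_treated: float
    rate_untreated: float


# ----------------------------------------------------------------------------
# random layout

_M_L, _M_INIT, _M_DISC, _M_SWITCH, _M_DEATH, _M_SUPPLY, _M_OFFSET = range(7)
_N_FIXED_MONTHLY = 7


def _baseline_draws(cfg: SimulationConfig, n: int, rng_stream: int):
    n_cov = len(cfg.baseline_covariates)
    # channels: covariates | age | sex | education | index date | prevalent flag
    #           | prevalent date | L0
    n_chan = n_cov + 6
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(rng_stream,)))
    U = rng.random((n, n_chan))
    cov = {}
    for j, spec in enumerate(cfg.baseline_covariates):
        cov[spec.name] = spec.draw(U[:, j])
    from scipy import stats

    age = 5.0 + np.exp(math.log(12.0) + 0.65 * stats.norm.ppf(np.clip(U[:, n_cov], 1e-12, 1 - 1e-12)))
    female = (U[:, n_cov + 1] < 0.413).astype(float)
    edu_u = U[:, n_cov + 2]
    education = np.where(edu_u < 0.17, "primary", np.where(edu_u < 0.67, "upper_secondary", "post_secondary"))
    start = pd.Timestamp(cfg.enrolment_start)
    span = (pd.Timestamp(cfg.enrolment_end) - start).days + 1
    index_day = (U[:, n_cov + 3] * span).astype(int)
    prevalent_u = U[:, n_cov + 4]
    prevalent = prevalent_u < cfg.prevalent_user_frac
    window_days = cfg.washout_check_window_months * DAYS_PER_INTERVAL
    prevalent_lag = 1 + (U[:, n_cov + 5] * (window_days - 1)).astype(int)
    cov_df = pd.DataFrame(cov)
    cov_df["age_at_index"] = age
    cov_df["female"] = female
    cov_df["age_z"] = (age - 18.0) / 10.0
    cov_df["edu_upper_secondary"] = (education == "upper_secondary").astype(float)
    cov_df["edu_post_secondary"] = (education == "post_secondary").astype(float)
    return cov_df, education, start, index_day, prevalent, prevalent_lag, U[:, n_cov + 5]


def _monthly_draws(cfg: SimulationConfig, n: int, rng_stream: int) -> np.ndarray:
    n_chan = _N_FIXED_MONTHLY + len(cfg.outcome_models)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(rng_stream,)))
    return rng.random((n, cfg.horizon_months, n_chan))


def _linpred(model: HazardModel, cov: pd.DataFrame, L: np.ndarray) -> np.ndarray:
    eta = np.full(len(cov), model.intercept)
    for name, coef in model.effects.items():
        if name == TV_CODE:
            eta = eta + coef * L
        else:
            eta = eta + coef * cov[name].to_numpy()
    return eta


def _simulate_paths(cfg: SimulationConfig, cov: pd.DataFrame, U: np.ndarray, regime: str):
    """Run the monthly process for all persons under a treatment regime.

    regime: "natural"  -- initiation/discontinuation/switch as modelled;
            "treat"    -- natural initiation timing but forced to initiate by
                          the last grace interval, then sustained forever;
            "never"    -- treatment withheld throughout.
    """
    n = len(cov)
    H = cfg.horizon_months
    outcomes = list(cfg.outcome_models)
    tv = cfg.tv_confounder_model
    L = np.zeros((n, H + 1))
    l0_eta = np.full(n, tv.intercept)
    for name, coef in tv.effects.items():
        l0_eta += coef * cov[name].to_numpy()
    # stationary-ish start: solve one persistence step at the no-treatment point
    L[:, 0] = (U[:, 0, _M_L] < _expit(l0_eta + tv.persistence * _expit(l0_eta))).astype(float)

    init_t = np.full(n, -1)
    disc_t = np.full(n, -1)
    switch_t = np.full(n, -1)
    death_day = np.full(n, np.inf)
    emig_day = np.full(n, np.inf)
    event_day = {k: np.full((n, H), -1, dtype=np.int32) for k in outcomes}
    alive = np.ones(n, dtype=bool)
    on_treat = np.zeros(n, dtype=bool)
    de_hazard = cfg.death_emigration_hazard

    for t in range(H):
        Lt = L[:, t]
        u_month = U[:, t, :]
        # death / emigration decided first; the exit day truncates this month
        u_de = u_month[:, _M_DEATH]
        exits = alive & (u_de < de_hazard)
        if de_hazard > 0:
            frac = u_de[exits] / de_hazard
            day = t * DAYS_PER_INTERVAL + (frac * DAYS_PER_INTERVAL).astype(int)
            is_death = frac < 0.5  # hazard split evenly between death and emigration
            dd, ed = death_day[exits], emig_day[exits]
            dd[is_death] = day[is_death]
            ed[~is_death] = day[~is_death]
            death_day[exits], emig_day[exits] = dd, ed
        exit_day = np.where(exits, np.minimum(death_day, emig_day), np.inf)

        # treatment mechanics
        if regime == "never":
            treated = np.zeros(n, dtype=bool)
        else:
            can_init = alive & (init_t < 0) & (t < cfg.grace_months)
            p_init = _expit(_linpred(cfg.initiation_model, cov, Lt))
            newly = can_init & (u_month[:, _M_INIT] < p_init)
            if regime == "treat" and t == cfg.grace_months:
                # the sustained-treatment regime behaves naturally during the
                # grace period (that is what the uncensored, unit-weight
                # initiation arm contributes there) and completes initiation
                # at the grace boundary: never-starters begin treatment in
                # the first post-grace interval
                newly = alive & (init_t < 0)
            init_t[newly] = t
            on_treat = on_treat | newly
            if regime == "natural":
                at_risk_disc = alive & on_treat & (init_t < t) & (disc_t < 0)
                p_disc = _expit(_linpred(cfg.discontinuation_model, cov, Lt))
                stopping = at_risk_disc & (u_month[:, _M_DISC] < p_disc)
                disc_t[stopping] = t
                on_treat = on_treat & ~stopping
                switching = alive & on_treat & (init_t < t) & (switch_t < 0) & (u_month[:, _M_SWITCH] < cfg.switch_prob)
                switch_t[switching] = t
            treated = alive & on_treat

        # outcome events, one per type per month at most
        day_offset = (u_month[:, _M_OFFSET] * DAYS_PER_INTERVAL).astype(int)
        for j, name in enumerate(outcomes):
            model = cfg.outcome_models[name]
            eta = _linpred(model, cov, Lt) + model.true_log_irr * treated
            hit = alive & (u_month[:, _N_FIXED_MONTHLY + j] < _expit(eta))
            if not cfg.recurrent and t:
                hit &= event_day[name][:, :t].max(axis=1) < 0
            day = t * DAYS_PER_INTERVAL + day_offset
            ok = hit & (day <= exit_day)
            event_day[name][ok, t] = day[ok]

        # confounder measured in month t, known at t+1; responds to treatment
        p_next = _expit(tv.intercept + tv.persistence * Lt + tv.treatment_effect * treated
                        + sum(c * cov[k].to_numpy() for k, c in tv.effects.items()))
        L[:, t + 1] = np.where(alive, (u_month[:, _M_L] < p_next).astype(float), L[:, t])
        alive = alive & ~exits

    return L, init_t, disc_t, switch_t, death_day, emig_day, event_day


# ----------------------------------------------------------------------------
# public operations

def simulate_cohort(config: SimulationConfig, return_truth: bool = False):
    """Generate pseudo-register tables (persons, diagnoses, dispensations, events).

    With ``return_truth=True`` also returns the latent :class:`GroundTruth`.
    """
    config.validate()
    n = config.n_individuals
    H = config.horizon_months
    cov, education, cal_start, index_day, prevalent, prevalent_lag, u_cls = _baseline_draws(config, n, rng_stream=1)
    U = _monthly_draws(config, n, rng_stream=2)
    L, init_t, disc_t, switch_t, death_day, emig_day, event_day = _simulate_paths(config, cov, U, "natural")

    index_date = cal_start + pd.to_timedelta(index_day, unit="D")
    person_id = np.arange(1, n + 1)

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": np.where(cov["female"].to_numpy() > 0, "F", "M"),
            "age_at_index": cov["age_at_index"].round(2),
            "index_date": index_date,
            "education_level": education,
            "death_date": index_date + pd.to_timedelta(np.where(np.isfinite(death_day), death_day, -1), unit="D"),
            "emigration_date": index_date + pd.to_timedelta(np.where(np.isfinite(emig_day), emig_day, -1), unit="D"),
        }
    )
    persons.loc[~np.isfinite(death_day), "death_date"] = pd.NaT
    persons.loc[~np.isfinite(emig_day), "emigration_date"] = pd.NaT
    for spec in config.baseline_covariates:
        persons[spec.name] = cov[spec.name].to_numpy()

    # dispensations: aligned to interval starts so that days-supply coverage
    # reconstructs the simulated exposure exactly (supply ambiguity is out of
    # scope); refill supplies in {30, 60, 90}, truncated at regime changes
    rows_pid, rows_day, rows_cls, rows_sup = [], [], [], []
    init_idx = np.where(init_t >= 0)[0]
    first_cls = np.where(u_cls < config.nonstimulant_frac, 1, 0)  # index into DRUG_CLASSES
    for i in init_idx:
        stop = disc_t[i] if disc_t[i] >= 0 else H
        stop = min(stop, int(math.ceil(min(death_day[i], emig_day[i], H * DAYS_PER_INTERVAL) / DAYS_PER_INTERVAL)))
        seg = [(int(init_t[i]), stop, DRUG_CLASSES[first_cls[i]])]
        if 0 <= switch_t[i] < stop:
            seg = [
                (int(init_t[i]), int(switch_t[i]), DRUG_CLASSES[first_cls[i]]),
                (int(switch_t[i]), stop, DRUG_CLASSES[1 - first_cls[i]]),
            ]
        refill = 0
        for a, b, cls in seg:
            day = a * DAYS_PER_INTERVAL
            end = b * DAYS_PER_INTERVAL
            while day < end:
                supply = int(min((1 + int(U[i, refill % H, _M_SUPPLY] * 3)) * 30, end - day))
                rows_pid.append(person_id[i])
                rows_day.append(day)
                rows_cls.append(cls)
                rows_sup.append(supply)
                day += supply
                refill += 1
    # prevalent users: a single pre-index dispensation inside the washout
    # check window, so the eligibility washout has something to exclude
    prev_idx = np.where(prevalent)[0]
    rows_pid.extend(person_id[prev_idx])
    rows_day.extend(-prevalent_lag[prev_idx])
    rows_cls.extend(np.where(u_cls[prev_idx] < config.nonstimulant_frac, DRUG_CLASSES[1], DRUG_CLASSES[0]))
    rows_sup.extend([30] * len(prev_idx))
    if rows_pid:
        rows_pid = np.asarray(rows_pid, dtype=int)
        dispensations = pd.DataFrame(
            {
                "person_id": rows_pid,
                "date": index_date[rows_pid - 1] + pd.to_timedelta(rows_day, unit="D"),
                "drug_class": rows_cls,
                "days_supply": np.asarray(rows_sup, dtype=int),
            }
        ).sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)
    else:
        dispensations = pd.DataFrame(columns=["person_id", "date", "drug_class", "days_supply"])

    # events
    ev_frames = []
    for name, mat in event_day.items():
        pi, ti = np.nonzero(mat >= 0)
        if pi.size:
            ev_frames.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[pi],
                        "date": index_date[pi] + pd.to_timedelta(mat[pi, ti], unit="D"),
                        "outcome_type": name,
                    }
                )
            )
    events = (
        pd.concat(ev_frames).sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)
        if ev_frames
        else pd.DataFrame(columns=["person_id", "date", "outcome_type"])
    )

    # diagnoses: the time-varying confounder surfaces as dated records; the
    # value measured in month t is recorded mid-month and read with lag one
    dg_frames = []
    base_on = np.where(L[:, 0] > 0)[0]
    if base_on.size:
        dg_frames.append(pd.DataFrame({"person_id": person_id[base_on], "date": index_date[base_on] - pd.Timedelta(days=15), "code": TV_CODE}))
    for t in range(H):
        on = np.where(L[:, t + 1] > 0)[0]
        if on.size:
            day = t * DAYS_PER_INTERVAL + 15
            dg_frames.append(pd.DataFrame({"person_id": person_id[on], "date": index_date[on] + pd.Timedelta(days=day), "code": TV_CODE}))
    diagnoses = (
        pd.concat(dg_frames).sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)
        if dg_frames
        else pd.DataFrame(columns=["person_id", "date", "code"])
    )

    tables = RegisterTables(persons, diagnoses, dispensations, events)
    if return_truth:
        truth = GroundTruth(cov, L, init_t, disc_t, switch_t, death_day, emig_day, event_day)
        return tables, truth
    return tables


def simulate_counterfactual_truth(
    config: SimulationConfig,
    n_mc: int,
    outcome_type: str | None = None,
    first_event_only: bool = True,
) -> TruthResult:
    """True marginal incidence rate ratio by forced-regime simulation.

    Each of ``n_mc`` fresh individuals is simulated twice: once forced to
    initiate within the grace period (natural timing, completed by the last
    grace interval) and remain treated, once never treated.  The marginal IRR
    is summarised exactly as the analysis pipeline summarises it -- a pooled
    discrete-time logistic model of the event indicator on regime and
    interval dummies over the counterfactual person-period data -- so that
    oracle and estimate target the same marginal quantity (an aggregate
    events-per-person-time ratio differs from it once depletion interacts
    with covariate heterogeneity).  A delta-method Monte-Carlo standard
    error on the IRR scale accompanies it.
    """
    config.validate()
    if n_mc <= 0:
        raise ValueError("n_mc must be positive")
    if outcome_type is None:
        if len(config.outcome_models) != 1:
            raise ValueError("outcome_type must be named when several outcomes are configured")
        outcome_type = next(iter(config.outcome_models))
    if outcome_type not in config.outcome_models:
        raise ValueError(f"unknown outcome_type {outcome_type!r}")

    cfg = replace(config, n_individuals=n_mc, recurrent=not first_event_only)
    cov, *_ = _baseline_draws(cfg, n_mc, rng_stream=3)
    H = cfg.horizon_months
    rows = {}
    res = {}
    var = {}
    for regime, stream in (("treat", 4), ("never", 5)):
        U = _monthly_draws(cfg, n_mc, rng_stream=stream)
        _, _, _, _, death_day, emig_day, event_day = _simulate_paths(cfg, cov, U, regime)
        mat = event_day[outcome_type] >= 0
        end = np.minimum(np.minimum(death_day, emig_day), H * DAYS_PER_INTERVAL)
        n_int = np.ceil(end / DAYS_PER_INTERVAL).astype(int)
        if first_event_only:
            first = np.where(mat.any(axis=1), mat.argmax(axis=1), H)
            months = np.minimum(n_int, first + 1)
        else:
            months = n_int
        total = int(months.sum())
        rep = np.repeat(np.arange(n_mc), months)
        starts = np.concatenate([[0], np.cumsum(months)[:-1]])
        t = np.arange(total) - np.repeat(starts, months)
        y = mat[rep, t].astype(float)
        rows[regime] = (t, y)
        ev_tot = float(y.sum())
        res[regime] = ev_tot / total
        resid = np.bincount(rep, weights=y, minlength=n_mc) - res[regime] * months
        var[regime] = float(np.sum(resid**2) / ev_tot**2)

    from ._glm import fit_pooled_logit

    t_all = np.concatenate([rows["treat"][0], rows["never"][0]])
    y_all = np.concatenate([rows["treat"][1], rows["never"][1]])
    g_all = np.concatenate([np.ones(rows["treat"][0].size), np.zeros(rows["never"][0].size)])
    ev_t = np.unique(t_all[y_all > 0])
    keep = np.isin(t_all, ev_t)
    fit = fit_pooled_logit(t_all[keep], g_all[keep, None], y_all[keep])
    irr = float(np.exp(fit.beta[0]))
    se_log = math.sqrt(var["treat"] + var["never"])  # aggregate-rate approximation
    return TruthResult(irr=irr, mc_se=float(irr * se_log), rate_treated=float(res["treat"]), rate_untreated=float(res["never"]))


_SCHEMAS = {
    "persons": ["person_id", "sex", "age_at_index", "index_date", "education_level", "death_date", "emigration_date"],
    "diagnoses": ["person_id", "date", "code"],
    "dispensations": ["person_id", "date", "drug_class", "days_supply"],
    "events": ["person_id", "date", "outcome_type"],
}


def write_register_tables(tables: RegisterTables, out_dir) -> dict:
    """Write the four register tables as RFC 4180 CSV with ISO-8601 dates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables._asdict().items():
        required = _SCHEMAS[name]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"{name} table missing required column {col!r}")
        if name == "dispensations" and len(df):
            bad = set(df["drug_class"]) - set(DRUG_CLASSES)
            if bad:
                raise ValueError(f"dispensations has unknown drug_class values: {sorted(bad)}")
            if (df["days_supply"] <= 0).any():
                raise ValueError("dispensations days_supply must be positive")
        out = df.copy()
        ordered = required + [c for c in out.columns if c not in required]
        out = out[ordered]
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        out.to_csv(path, index=False)
        written[name] = path
    return written
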