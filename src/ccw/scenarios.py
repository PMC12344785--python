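"""Canonical validation scenarios with known ground truth.

These configurations define the simulation studies that validate the
pipeline: a strict null with confounded initiation and discontinuation, an
effect-recovery scenario with a time-varying confounder, an immortal-time
demonstration, a negative-control run, and a scaled-down bootstrap coverage
study.  Tests and the acceptance script both run them, so the study
conditions live in one place.

The consistency scenarios switch the treatment effect on the confounder
dynamics off (so the marginal null is a true null) and run without weight
truncation (truncation trades a known bias for variance and is validated
separately); see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .clone_censor import TrialSpec
from .ipcw import CensoringModelSpec
from .pipeline import TrialData, estimate_on_index, naive_initiator_irr
from .synthetic_registry import (
    HazardModel,
    SimulationConfig,
    TvConfounderModel,
    simulate_cohort,
    simulate_counterfactual_truth,
)

__all__ = [
    "OUTCOME",
    "FULL_COVARIATES",
    "LEAN_COVARIATES",
    "no_feedback_confounder",
    "effect_config",
    "null_config",
    "coverage_config",
    "trial_spec",
    "censoring_spec",
    "run_replicates",
    "run_coverage_study",
]

OUTCOME = "substance_misuse"

FULL_COVARIATES = (
    "female",
    "age_z",
    "edu_upper_secondary",
    "edu_post_secondary",
    "psych_comorbidity",
    "prior_event",
    "comed_psychotropic",
    "hc_visits",
    "tv_confounder",
)
LEAN_COVARIATES = ("psych_comorbidity", "prior_event", "tv_confounder")


def no_feedback_confounder() -> TvConfounderModel:
    """Confounder dynamics without a treatment effect (true-null compatible)."""
    return TvConfounderModel(-2.3, 2.0, 0.0, {"psych_comorbidity": 0.8})


def effect_config(n: int, seed: int, true_irr: float = 0.85) -> SimulationConfig:
    """Sustained-treatment effect with baseline and time-varying confounding.

    Initiation depends on baseline covariates and the lagged confounder;
    discontinuation depends on the confounder; the outcome hazard carries
    covariate terms, the confounder, and ``log(true_irr)`` under treatment.
    """
    cfg = SimulationConfig(n_individuals=n, seed=seed, tv_confounder_model=no_feedback_confounder())
    base = cfg.outcome_models[OUTCOME]
    return cfg.with_outcome(OUTCOME, replace(base, true_log_irr=math.log(true_irr)))


def null_config(n: int, seed: int) -> SimulationConfig:
    """The effect scenario with the treatment effect switched off."""
    return effect_config(n, seed, true_irr=1.0)


def coverage_config(n: int, seed: int, true_irr: float = 0.85) -> SimulationConfig:
    """Reduced scenario for the bootstrap coverage study.

    Only two baseline covariates and the time-varying confounder carry
    effects, so the lean censoring model is correctly specified and each
    pipeline refit stays cheap.
    """
    return SimulationConfig(
        n_individuals=n,
        seed=seed,
        tv_confounder_model=no_feedback_confounder(),
        initiation_model=HazardModel(-0.85, {"psych_comorbidity": -0.5, "prior_event": -0.3, "tv_confounder": -0.4}),
        discontinuation_model=HazardModel(-2.75, {"psych_comorbidity": 0.3, "tv_confounder": 1.2}),
        outcome_models={
            OUTCOME: HazardModel(
                -5.11,
                {"psych_comorbidity": 0.5, "prior_event": 0.8, "tv_confounder": 0.8},
                math.log(true_irr),
            )
        },
    )


def trial_spec(recurrent: bool = False) -> TrialSpec:
    return TrialSpec(outcome_type=OUTCOME, recurrent=recurrent)


def censoring_spec(covariates=FULL_COVARIATES, truncation: float = 100.0) -> CensoringModelSpec:
    return CensoringModelSpec(tuple(covariates), truncation_percentile=truncation)


def run_replicates(
    config: SimulationConfig,
    n_replicates: int,
    seed0: int,
    covariates=FULL_COVARIATES,
    truncation: float = 100.0,
    use_weights: bool = True,
    naive: bool = False,
):
    """Run the full pipeline on ``n_replicates`` fresh cohorts.

    Returns a dict with the per-replicate IRRs (and naive ever/never IRRs
    when requested).
    """
    spec = trial_spec()
    cens = censoring_spec(covariates, truncation)
    irrs, naives = [], []
    for k in range(n_replicates):
        tables = simulate_cohort(replace(config, seed=seed0 + k))
        data = TrialData.from_tables(tables, spec, cens.covariates)
        res = estimate_on_index(data, np.arange(data.n), cens, use_weights=use_weights)
        irrs.append(res.irr)
        if naive:
            naives.append(naive_initiator_irr(data))
    out = {"irr": np.asarray(irrs)}
    if naive:
        out["naive_irr"] = np.asarray(naives)
    return out


def run_coverage_study(
    n_replicates: int = 100,
    n: int = 5000,
    n_boot: int = 100,
    seed: int = 0,
    true_irr: float = 0.85,
) -> dict:
    """Scaled-down bootstrap coverage study.

    Simulates ``n_replicates`` cohorts from :func:`coverage_config`, runs the
    full pipeline with a person-level bootstrap on each, and counts how often
    the 95% percentile CI covers the true marginal IRR.
    """
    from .inference import BootstrapSpec, bootstrap_ci_from_data

    base = coverage_config(n, seed, true_irr)
    truth = simulate_counterfactual_truth(
        replace(base, seed=seed + 1_000_000), max(200_000, 20 * n), outcome_type=OUTCOME
    )
    spec = trial_spec()
    cens = censoring_spec(LEAN_COVARIATES, truncation=100.0)
    covered = 0
    failures = 0
    cis = []
    for k in range(n_replicates):
        tables = simulate_cohort(replace(base, seed=seed + k))
        data = TrialData.from_tables(tables, spec, cens.covariates)
        boot = BootstrapSpec(n_boot=n_boot, seed=seed + 10_000 + k, ci_method="percentile")
        try:
            res = bootstrap_ci_from_data(data, cens, boot)
        except RuntimeError:
            failures += 1
            continue
        cis.append((res.ci_low, res.ci_high))
        if res.ci_low <= truth.irr <= res.ci_high:
            covered += 1
    return {
        "covered": covered,
        "n_replicates": n_replicates,
        "failures": failures,
        "truth": truth.irr,
        "truth_mc_se": truth.mc_se,
        "cis": cis,
    }
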