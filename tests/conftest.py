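import numpy as np
import pandas as pd
import pytest

import ccw
from ccw.scenarios import (
    FULL_COVARIATES,
    OUTCOME,
    effect_config,
    null_config,
    run_replicates,
    trial_spec,
    censoring_spec,
)
from ccw.synthetic_registry import simulate_counterfactual_truth


def small_tables(n=300, seed=5, **overrides):
    cfg = ccw.SimulationConfig(n_individuals=n, seed=seed, **overrides)
    return ccw.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic register set shared across cheap tests."""
    return small_tables()


@pytest.fixture(scope="session")
def null_study():
    """Ten replicates of the confounded strict-null scenario at n=20000.

    Used by the null-recovery and immortal-time acceptance checks; the
    replicates double as the Monte-Carlo error estimate (with a Student-t
    critical value, since the SE itself is estimated from the replicates).
    """
    return run_replicates(null_config(20000, 0), n_replicates=10, seed0=211, naive=True)


@pytest.fixture(scope="session")
def effect_study():
    """Effect-recovery scenario: truth plus weighted and unweighted replicates."""
    cfg = effect_config(20000, 0)
    truth = simulate_counterfactual_truth(cfg, 250_000, outcome_type=OUTCOME)
    weighted = run_replicates(cfg, n_replicates=8, seed0=431)
    unweighted = run_replicates(cfg, n_replicates=8, seed0=431, use_weights=False)
    return {"truth": truth, "weighted": weighted["irr"], "unweighted": unweighted["irr"], "config": cfg}


@pytest.fixture(scope="session")
def effect_run_balance():
    """One full effect-scenario run with balance diagnostics at end of grace."""
    from ccw.pipeline import TrialData, estimate_on_index

    cfg = effect_config(20000, 0)
    tables = ccw.simulate_cohort(cfg)
    cens = censoring_spec(FULL_COVARIATES, truncation=100.0)
    data = TrialData.from_tables(tables, trial_spec(), cens.covariates)
    return estimate_on_index(data, np.arange(data.n), cens, balance_at=cfg.grace_months)


def panel_from_arrays(t, event, censored, weight=None, arm=None, person=None, py=None):
    """Hand-build a person-interval panel DataFrame for unit tests."""
    n = len(t)
    df = pd.DataFrame(
        {
            "person_id": person if person is not None else np.zeros(n, dtype=int),
            "clone_arm": arm if arm is not None else ["initiation"] * n,
            "t": t,
            "event": event,
            "censored": censored,
            "person_years": py if py is not None else np.full(n, 1 / 12),
        }
    )
    if weight is not None:
        df["weight"] = weight
    return df
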