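"""Covariate balance, weight audits, and the negative-control harness.

Balance between the two strategy arms is assessed among clones still at risk
(uncensored) at the end of the grace period, with standardized mean
differences; |SMD| < 0.10 is the conventional adequacy threshold.  The
negative-control harness reruns the whole pipeline on an outcome generated
independently of treatment; an estimate away from the null there flags
residual confounding or a design defect.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .clone_censor import ARM_INITIATION, ARM_NON_INITIATION, TrialSpec
from .estimation import EstimateResult
from .ipcw import CensoringModelSpec
from .synthetic_registry import RegisterTables

__all__ = [
    "standardized_mean_difference",
    "balance_table",
    "run_negative_control",
    "naive_initiator_irr",
]


def standardized_mean_difference(
    values_a,
    values_b,
    weights_a=None,
    weights_b=None,
) -> float:
    """(m_a - m_b) / sqrt((v_a + v_b) / 2) with weighted means and variances.

    The sign convention is group A minus group B.  Binary covariates are
    expected as 0/1 indicators.  Rescaling either group's weights by a
    constant leaves the value unchanged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    wa = np.ones(a.size) if weights_a is None else np.asarray(weights_a, dtype=float)
    wb = np.ones(b.size) if weights_b is None else np.asarray(weights_b, dtype=float)
    ma = np.sum(wa * a) / np.sum(wa)
    mb = np.sum(wb * b) / np.sum(wb)
    va = np.sum(wa * (a - ma) ** 2) / np.sum(wa)
    vb = np.sum(wb * (b - mb) ** 2) / np.sum(wb)
    pooled = (va + vb) / 2.0
    if pooled <= 0.0:
        if math.isclose(ma, mb, abs_tol=1e-12):
            return 0.0
        raise ZeroDivisionError("zero pooled variance with unequal means: SMD undefined")
    return float((ma - mb) / math.sqrt(pooled))


def balance_table(panel: pd.DataFrame, covariates, at_interval: int) -> pd.DataFrame:
    """Unweighted and weighted SMDs among clones at risk at ``at_interval``.

    The panel must carry clone arms, the censoring indicator and weights.
    Returns one row per covariate plus flags at the 0.10 threshold.
    """
    sub = panel[(panel["t"] == at_interval) & (panel["censored"] == 0)]
    groups = {}
    for arm in (ARM_INITIATION, ARM_NON_INITIATION):
        g = sub[sub["clone_arm"] == arm]
        if not len(g):
            raise ValueError(f"no at-risk rows for arm {arm!r} at interval {at_interval}")
        groups[arm] = g
    rows = []
    for cov in covariates:
        if cov not in panel.columns:
            raise ValueError(f"covariate {cov!r} missing from panel")
        a, b = groups[ARM_INITIATION], groups[ARM_NON_INITIATION]
        smd_u = standardized_mean_difference(a[cov], b[cov])
        smd_w = standardized_mean_difference(a[cov], b[cov], a["weight"], b["weight"])
        rows.append(
            {
                "covariate": cov,
                "smd_unweighted": smd_u,
                "smd_weighted": smd_w,
                "flag_unweighted": abs(smd_u) >= 0.10,
                "flag_weighted": abs(smd_w) >= 0.10,
                "at_interval": at_interval,
            }
        )
    return pd.DataFrame(rows)


def run_negative_control(
    tables: RegisterTables,
    trial_spec: TrialSpec,
    cens_spec: CensoringModelSpec,
    control_outcome: str = "type1_diabetes",
) -> EstimateResult:
    """Re-run the full pipeline on a negative-control outcome.

    The control outcome must exist in the events table; under a process
    independent of treatment its IRR should be compatible with 1, and a
    clearly non-null estimate flags bias (the harness reports, it does not
    assert).
    """
    from dataclasses import replace

    from .pipeline import run_ccw_estimate

    if control_outcome not in set(tables.events["outcome_type"].unique()):
        raise ValueError(f"control outcome {control_outcome!r} absent from events table")
    spec = replace(trial_spec, outcome_type=control_outcome)
    return run_ccw_estimate(tables, spec, cens_spec)


def naive_initiator_irr(*args, **kwargs):
    """Immortal-time-biased ever-initiator comparison (see :mod:`ccw.pipeline`)."""
    from .pipeline import naive_initiator_irr as _impl

    return _impl(*args, **kwargs)
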