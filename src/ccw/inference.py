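"""Person-level nonparametric bootstrap and Wald contrasts.

Confidence intervals come from full re-samples of individuals: each resample
draws persons with replacement at the original cohort size and reruns the
entire pipeline -- cloning, censoring, censoring-model fitting, weighting,
outcome fitting -- so the interval reflects every estimated stage.  The
default is 500 resamples with percentile intervals on the log-IRR scale,
back-transformed (hence equivariant under exp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .estimation import EstimateResult
from .ipcw import CensoringModelSpec
from .clone_censor import TrialSpec
from .pipeline import TrialData, estimate_on_index
from .synthetic_registry import RegisterTables

__all__ = ["BootstrapSpec", "bootstrap_ci", "bootstrap_ci_from_data", "wald_compare"]


@dataclass(frozen=True)
class BootstrapSpec:
    n_boot: int = 500
    seed: int = 0
    ci_method: str = "percentile"  # percentile | normal
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_boot < 2:
            raise ValueError("n_boot must be at least 2")
        if self.ci_method not in ("percentile", "normal"):
            raise ValueError("ci_method must be 'percentile' or 'normal'")


def bootstrap_ci_from_data(
    data: TrialData,
    cens_spec: CensoringModelSpec,
    boot_spec: BootstrapSpec,
    keep_distribution: bool = False,
) -> EstimateResult:
    """Bootstrap on a prebuilt :class:`TrialData` (exposure timelines are
    deterministic per person, so they are reused across resamples)."""
    n = data.n
    warm: dict = {}
    base = estimate_on_index(data, np.arange(n), cens_spec, warm_cache=warm)
    rng = np.random.default_rng(boot_spec.seed)
    draws = []
    failures = 0
    for _ in range(boot_spec.n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            r = estimate_on_index(data, idx, cens_spec, warm_cache=dict(warm))
            draws.append(r.log_irr)
        except (ValueError, RuntimeError, FloatingPointError):
            failures += 1
    if failures > 0.10 * boot_spec.n_boot:
        raise RuntimeError(f"{failures}/{boot_spec.n_boot} bootstrap resamples failed")
    draws = np.asarray(draws)
    se = float(draws.std(ddof=1))
    a = boot_spec.alpha
    if boot_spec.ci_method == "percentile":
        lo, hi = np.percentile(draws, [100 * a / 2, 100 * (1 - a / 2)])
    else:
        z = stats.norm.ppf(1 - a / 2)
        lo, hi = base.log_irr - z * se, base.log_irr + z * se
    out = EstimateResult(
        irr=base.irr,
        log_irr=base.log_irr,
        ci_low=float(math.exp(lo)),
        ci_high=float(math.exp(hi)),
        se_log_irr=se,
        weighted_rate_per_1000py=base.weighted_rate_per_1000py,
        weighted_events=base.weighted_events,
        weighted_person_years=base.weighted_person_years,
        model_meta=base.model_meta,
        diagnostics=dict(base.diagnostics, bootstrap_failures=failures, n_boot=boot_spec.n_boot),
        person_ids=base.person_ids,
    )
    if keep_distribution:
        out.diagnostics["bootstrap_log_irr"] = draws
    return out


def bootstrap_ci(
    tables: RegisterTables,
    trial_spec: TrialSpec,
    cens_spec: CensoringModelSpec,
    boot_spec: BootstrapSpec,
    keep_distribution: bool = False,
) -> EstimateResult:
    """Full-pipeline bootstrap confidence interval from register tables."""
    data = TrialData.from_tables(tables, trial_spec, cens_spec.covariates)
    return bootstrap_ci_from_data(data, cens_spec, boot_spec, keep_distribution)


def wald_compare(result_a: EstimateResult, result_b: EstimateResult) -> tuple[float, float]:
    """Wald z and two-sided p for a difference between two log IRRs.

    The two estimates must come from independent subgroups, each carrying a
    bootstrap standard error of the log IRR.
    """
    for r, side in ((result_a, "a"), (result_b, "b")):
        if r.se_log_irr is None:
            raise ValueError(f"result_{side} carries no bootstrap SE of log_irr")
    if result_a.person_ids is not None and result_b.person_ids is not None:
        if result_a.person_ids & result_b.person_ids:
            raise ValueError("subgroups overlap; the Wald contrast assumes independence")
    z = (result_a.log_irr - result_b.log_irr) / math.sqrt(result_a.se_log_irr**2 + result_b.se_log_irr**2)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p
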