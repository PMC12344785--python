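"""Inverse probability of censoring weights from pooled logistic models.

One composite censoring model is fitted per clone arm (the two arms deviate
through different mechanisms, so their censoring processes differ).  The
model regresses the censoring indicator on interval dummies plus baseline and
lag-one time-varying covariates, over all person-intervals at risk of
artificial censoring.  Time is saturated: intervals with no censoring events
among the at-risk rows get fitted censoring probability exactly zero (the
maximum-likelihood limit of the dummy model), which keeps the weights flat
where deviation is structurally impossible.

The unstabilized weight at interval t is the running product of inverse
conditional probabilities of remaining uncensored through t; the stabilized
variant multiplies by the analogous product from a covariate-free
(time-only) model.  Weights are truncated at a per-arm percentile (linear
interpolation between order statistics, numpy's default) to limit the
influence of extreme values; the study design this package implements uses
the 99.5th centile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clone_censor import ARM_INITIATION, ARM_NON_INITIATION
from ._glm import fit_pooled_logit

__all__ = [
    "CensoringModelSpec",
    "WeightDiagnostics",
    "CensoringModelFit",
    "fit_censoring_model",
    "compute_ipc_weights",
    "truncate_weights",
]


@dataclass(frozen=True)
class CensoringModelSpec:
    """Covariates and form of the per-arm censoring models."""

    covariates: tuple[str, ...]
    time_form: str = "dummies"          # "dummies" | "poly<k>"
    truncation_percentile: float = 99.5
    stabilized: bool = False
    # the initiation arm censors through two distinct mechanisms -- "never
    # started treatment" at the end of grace and "discontinued or switched"
    # afterwards -- whose covariate relationships differ; fitting them in one
    # model lets the grace-end mass dilute the time-varying coefficients and
    # leaves the discontinuation selection under-corrected
    separate_grace_model: bool = True

    def __post_init__(self):
        if not (50.0 < self.truncation_percentile <= 100.0):
            raise ValueError("truncation_percentile must lie in (50, 100]")
        if self.time_form != "dummies" and not self.time_form.startswith("poly"):
            raise ValueError("time_form must be 'dummies' or 'poly<k>'")


@dataclass
class WeightDiagnostics:
    arm: dict = field(default_factory=dict)  # arm -> summary dict

    def to_dict(self) -> dict:
        return {"arms": self.arm}


@dataclass
class CensoringModelFit:
    """Per-row probabilities of remaining uncensored, plus fit metadata."""

    p_uncensored: pd.Series      # aligned with the panel index
    p_uncensored_marginal: pd.Series | None
    n_censored: dict
    converged: bool


def _design(panel: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for name in covariates:
        if name not in panel.columns:
            raise ValueError(f"covariate {name!r} missing from panel")
        cols.append(panel[name].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(panel), 0))


def _fit_censoring_arrays(t: np.ndarray, Xc: np.ndarray | None, y: np.ndarray, time_form: str, start=None):
    """Fit P(censored at t | at risk) on flat arrays; return (p_cens, converged, fit).

    With interval dummies, intervals whose at-risk rows are all uncensored
    (or all censored) receive their empirical probability 0 (or 1) directly,
    which is the maximum-likelihood limit of the saturated-in-time model;
    only mixed intervals enter the Newton fit.
    """
    p_cens = np.zeros(t.size)
    fit = None
    if y.sum() == 0:
        return p_cens, True, None  # no artificial censoring: probability 1 throughout
    if time_form == "dummies":
        t_vals, t_inv = np.unique(t, return_inverse=True)
        n_c = np.bincount(t_inv, weights=y)
        n_t = np.bincount(t_inv)
        mixed = (n_c > 0) & (n_c < n_t)
        in_fit = mixed[t_inv]
        ok = True
        if in_fit.any():
            X = Xc[in_fit] if Xc is not None else None
            fit = fit_pooled_logit(t[in_fit], X, y[in_fit], start=start)
            p_cens[in_fit] = fit.predict(t[in_fit], X)
            ok = fit.converged
        p_cens[(n_c == n_t)[t_inv]] = 1.0
    elif time_form.startswith("poly"):
        from ._glm import fit_logit

        degree = int(time_form[4:] or 2)
        tt = t.astype(float)
        blocks = [np.ones(t.size)] + [tt**k for k in range(1, degree + 1)]
        if Xc is not None and Xc.size:
            blocks.append(Xc)
        X = np.column_stack(blocks)
        fit = fit_logit(X, y)
        p_cens = fit.predict(X)
        ok = fit.converged
        fit = None  # dense fits are not reused as warm starts
    else:
        raise ValueError(f"unknown time_form {time_form!r}")
    return p_cens, ok, fit


def _fit_one_arm(sub: pd.DataFrame, spec: CensoringModelSpec, grace_months: int | None = None):
    """Fit P(censored at t | at risk) within one arm; return p_uncensored."""
    y = sub["censored"].to_numpy(dtype=float)
    t = sub["t"].to_numpy()
    X = _design(sub, spec.covariates) if spec.covariates else None
    if grace_months is not None and spec.separate_grace_model:
        p_cens = np.zeros(t.size)
        ok = True
        for m in (t < grace_months, t == grace_months, t > grace_months):
            if m.any():
                p_m, ok_m, _ = _fit_censoring_arrays(t[m], X[m] if X is not None else None, y[m], spec.time_form)
                p_cens[m] = p_m
                ok &= ok_m
    else:
        p_cens, ok, _ = _fit_censoring_arrays(t, X, y, spec.time_form)
    return 1.0 - p_cens, ok


def fit_censoring_model(
    panel: pd.DataFrame, spec: CensoringModelSpec, grace_months: int | None = None
) -> CensoringModelFit:
    """Fit the per-arm pooled logistic censoring models.

    The panel must contain the ``censored`` indicator (1 on the first
    censored interval of a clone) and rows only up to and including that
    interval.  Returns conditional probabilities of remaining uncensored for
    every person-interval row.  With ``grace_months`` given (and
    ``spec.separate_grace_model``), the initiation arm's grace-end and
    post-grace censoring mechanisms are modelled separately.
    """
    for col in ("clone_arm", "censored", "t"):
        if col not in panel.columns:
            raise ValueError(f"panel missing required column {col!r}")
    p = pd.Series(np.ones(len(panel)), index=panel.index)
    p_marg = pd.Series(np.ones(len(panel)), index=panel.index) if spec.stabilized else None
    n_cens = {}
    converged = True
    for arm in (ARM_INITIATION, ARM_NON_INITIATION):
        mask = panel["clone_arm"] == arm
        sub = panel[mask]
        if not len(sub):
            raise ValueError(f"arm {arm!r} is empty")
        g = grace_months if arm == ARM_INITIATION else None
        p_arm, ok = _fit_one_arm(sub, spec, g)
        converged &= ok
        p.loc[mask] = p_arm
        n_cens[arm] = int(sub["censored"].sum())
        if spec.stabilized:
            marg_spec = CensoringModelSpec(covariates=(), time_form=spec.time_form,
                                           truncation_percentile=spec.truncation_percentile)
            p_m, _ = _fit_one_arm(sub, marg_spec, g)
            p_marg.loc[mask] = p_m
    return CensoringModelFit(p_uncensored=p, p_uncensored_marginal=p_marg, n_censored=n_cens, converged=converged)


def compute_ipc_weights(
    panel: pd.DataFrame,
    fit: CensoringModelFit,
    stabilized: bool = False,
) -> pd.DataFrame:
    """Attach cumulative-product IPC weights to uncensored person-intervals.

    ``w_it = prod_{k<=t} 1 / p_ik`` over the clone's uncensored intervals;
    the stabilized variant multiplies by the running product of marginal
    uncensoring probabilities.  Weights on censored rows are undefined (NaN).
    """
    out = panel.copy()
    p = fit.p_uncensored.to_numpy()
    if np.any(p <= 0.0) and np.any((out["censored"].to_numpy() == 0) & (p <= 0.0)):
        raise FloatingPointError("zero probability of remaining uncensored on an uncensored row")
    out["p_uncensored"] = p
    keys = [out["person_id"], out["clone_arm"]]
    logs = pd.Series(-np.log(np.maximum(p, 1e-300)), index=out.index)
    w = np.exp(logs.groupby(keys).cumsum())
    if stabilized:
        if fit.p_uncensored_marginal is None:
            raise ValueError("model was not fitted with stabilized=True")
        logs_m = pd.Series(np.log(np.maximum(fit.p_uncensored_marginal.to_numpy(), 1e-300)), index=out.index)
        w = w * np.exp(logs_m.groupby(keys).cumsum())
    out["weight_raw"] = np.where(out["censored"] == 0, w, np.nan)
    out["weight"] = out["weight_raw"]
    return out


def truncate_weights(panel: pd.DataFrame, percentile: float = 99.5) -> tuple[pd.DataFrame, WeightDiagnostics]:
    """Cap weights at the per-arm percentile (computed within each arm)."""
    if not (50.0 < percentile <= 100.0):
        raise ValueError("percentile must lie in (50, 100]")
    if "weight_raw" not in panel.columns:
        raise ValueError("panel has no weights; run compute_ipc_weights first")
    out = panel.copy()
    diags = WeightDiagnostics()
    for arm, sub in out.groupby("clone_arm"):
        w = sub["weight_raw"].dropna()
        if not len(w):
            continue
        thr = float(np.percentile(w, percentile))
        capped = np.minimum(sub["weight_raw"], thr)
        out.loc[sub.index, "weight"] = capped
        ess = float(capped.dropna().sum() ** 2 / (capped.dropna() ** 2).sum())
        diags.arm[arm] = {
            "mean_before": float(w.mean()),
            "max_before": float(w.max()),
            "threshold": thr,
            "mean_after": float(capped.mean()),
            "max_after": float(capped.max()),
            "effective_sample_size": ess,
            "n_weighted_rows": int(len(w)),
        }
    return out, diags
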