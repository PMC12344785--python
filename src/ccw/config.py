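"""Run configuration, orchestration, and reproducible result bundles.

A :class:`RunConfig` describes one emulated trial end to end: where the
register tables come from (paths, or a simulation config), the trial
specification, the censoring-model specification, and the bootstrap.  One
master seed is split deterministically into the simulator and bootstrap
streams.  ``run_trial`` writes results JSON, a balance CSV, cumulative
incidence curves and a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clone_censor import ARM_INITIATION, ARM_NON_INITIATION, TrialSpec
from .cohort import EligibilitySpec, load_register_tables
from .inference import BootstrapSpec, bootstrap_ci_from_data, wald_compare
from .ipcw import CensoringModelSpec
from .pipeline import TrialData, estimate_on_index
from .synthetic_registry import TV_CODE, HazardModel, SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_trial", "run_trial_suite", "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = (
    "female",
    "age_z",
    "edu_upper_secondary",
    "edu_post_secondary",
    "psych_comorbidity",
    "prior_event",
    "comed_psychotropic",
    "hc_visits",
    TV_CODE,
)


@dataclass(frozen=True)
class RunConfig:
    trial: TrialSpec
    censoring: CensoringModelSpec = field(default_factory=lambda: CensoringModelSpec(DEFAULT_COVARIATES))
    bootstrap: BootstrapSpec | None = None
    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    output_dir: str = "ccw_results"
    seed: int = 0
    label: str | None = None
    # optional pandas query on the persons table (e.g. 'sex == "F"'),
    # applied before eligibility: subgroup analyses are separate runs on
    # subgroup-restricted cohorts
    subgroup_query: str | None = None

    def __post_init__(self):
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("exactly one of input_dir or simulation must be given")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        elig = EligibilitySpec(**raw.get("eligibility", {}))
        trial = TrialSpec(eligibility=elig, **raw["trial"])
        cens_raw = raw.get("censoring", {})
        cens = CensoringModelSpec(covariates=tuple(cens_raw.pop("covariates", DEFAULT_COVARIATES)), **cens_raw)
        boot = BootstrapSpec(**raw["bootstrap"]) if "bootstrap" in raw else None
        sim = None
        if "simulation" in raw:
            sim_raw = dict(raw["simulation"])
            if "outcome_models" in sim_raw:
                sim_raw["outcome_models"] = {k: HazardModel(**v) for k, v in sim_raw["outcome_models"].items()}
            sim = SimulationConfig(**sim_raw)
        return RunConfig(
            trial=trial,
            censoring=cens,
            bootstrap=boot,
            input_dir=raw.get("input_dir"),
            simulation=sim,
            output_dir=raw.get("output_dir", "ccw_results"),
            seed=int(raw.get("seed", 0)),
            label=raw.get("label"),
            subgroup_query=raw.get("subgroup_query"),
        )


def _load_or_simulate(config: RunConfig):
    if config.input_dir is not None:
        return load_register_tables(config.input_dir)
    sim = replace(config.simulation, seed=int(np.random.SeedSequence(config.seed, spawn_key=(11,)).generate_state(1)[0] % (2**31)))
    return simulate_cohort(sim)


def _config_digest(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **{f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}}
        if isinstance(o, dict):
            return {k: enc(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    return hashlib.sha256(json.dumps(enc(config), sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_trial(config: RunConfig, tables=None) -> dict:
    """Run one emulated trial; write and return the result bundle."""
    if config.trial.outcome_type is None:
        raise ValueError("trial outcome_type must be set")
    if tables is None:
        tables = _load_or_simulate(config)
    if config.trial.outcome_type not in set(tables.events["outcome_type"].unique()):
        raise ValueError(f"outcome type {config.trial.outcome_type!r} absent from events table")
    if config.subgroup_query:
        tables = tables._replace(persons=tables.persons.query(config.subgroup_query))

    data = TrialData.from_tables(tables, config.trial, config.censoring.covariates)
    balance_at = config.trial.grace_months if config.trial.comparison == "initiation_vs_none" else None
    if config.bootstrap is not None:
        boot = replace(config.bootstrap, seed=int(np.random.SeedSequence(config.seed, spawn_key=(13,)).generate_state(1)[0] % (2**31)))
        result = bootstrap_ci_from_data(data, config.censoring, boot)
        point = estimate_on_index(data, np.arange(data.n), config.censoring, balance_at=balance_at, with_panel=True)
        result.diagnostics.update({k: v for k, v in point.diagnostics.items() if k not in result.diagnostics})
    else:
        result = estimate_on_index(data, np.arange(data.n), config.censoring, balance_at=balance_at, with_panel=True)

    panel = result.diagnostics.pop("_panel", None)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label = config.label or config.trial.outcome_type

    bundle = {
        "label": label,
        "outcome": config.trial.outcome_type,
        "result": result.to_dict(),
        "exclusion_log": data.exclusion_log.to_dict(orient="records"),
        "manifest": {"config_digest": _config_digest(config), "seed": config.seed, "n_eligible": int(data.n)},
    }
    (out_dir / f"{label}_result.json").write_text(json.dumps(bundle, indent=2, default=float))
    if "balance" in result.diagnostics:
        pd.DataFrame(result.diagnostics["balance"]).to_csv(out_dir / f"{label}_balance.csv", index=False)
    if panel is not None and not config.trial.recurrent:
        from .estimation import cumulative_incidence_curve

        curves = []
        for arm in (ARM_INITIATION, ARM_NON_INITIATION):
            c = cumulative_incidence_curve(panel, arm)
            c.insert(0, "arm", arm)
            curves.append(c)
        pd.concat(curves, ignore_index=True).to_csv(out_dir / f"{label}_cumulative_incidence.csv", index=False)
    bundle["_result_obj"] = result
    return bundle


def run_trial_suite(configs: list[RunConfig], subgroup_pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Run several trial configurations and tabulate IRRs side by side.

    ``subgroup_pairs`` names pairs of config labels whose IRRs should be
    contrasted with a Wald test (requires bootstrap SEs in both runs).
    """
    if not configs:
        raise ValueError("empty config list")
    labels = [c.label or c.trial.outcome_type for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("config labels must be unique within a suite")

    bundles = {}
    rows = []
    for config, label in zip(configs, labels):
        bundle = run_trial(config)
        bundles[label] = bundle["_result_obj"]
        r = bundle["result"]
        rows.append(
            {
                "label": label,
                "outcome": bundle["outcome"],
                "recurrent": config.trial.recurrent,
                "irr": r["irr"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "rate_initiation": r["weighted_rate_per_1000py"].get(ARM_INITIATION),
                "rate_non_initiation": r["weighted_rate_per_1000py"].get(ARM_NON_INITIATION),
                "wald_z": np.nan,
                "wald_p": np.nan,
            }
        )
    table = pd.DataFrame(rows)
    for a, b in subgroup_pairs or []:
        z, p = wald_compare(bundles[a], bundles[b])
        table.loc[table["label"] == a, ["wald_z", "wald_p"]] = (z, p)
    return table
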