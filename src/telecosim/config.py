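"""Configuration loading and validation.

A single YAML file drives the pipeline, with sections ``population``,
``cost_inputs``, ``evaluation``, ``scenario`` and ``experiment``. Every
section is optional; omitted fields fall back to the study defaults baked
into the corresponding dataclasses. ``validate_config`` re-checks all type
invariants (probability sums, non-negative prices, grid steps) and returns
one finding per violation with a field path, rather than stopping at the
first problem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace
from pathlib import Path

import yaml

from .costs import CostInputs, CostModelError, TariffParams
from .des import DistributionSpec, ScenarioConfig, SimulationError
from .experiments import ExperimentPlan, build_grid
from .population import ConfigurationError, PopulationParams

__all__ = [
    "load_config",
    "build_population_params",
    "build_cost_inputs",
    "build_scenario",
    "build_experiment_plan",
    "validate_config",
]


def load_config(path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    try:
        cfg = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path} must contain a mapping at top level")
    return cfg


def _apply(dc, section: dict, path: str):
    valid = {f.name for f in dataclasses.fields(dc)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigurationError(f"{path}: unknown fields {sorted(unknown)}")
    return replace(dc, **section)


def build_population_params(cfg: dict) -> PopulationParams:
    return _apply(PopulationParams(), dict(cfg.get("population") or {}), "population")


def build_cost_inputs(cfg: dict) -> CostInputs:
    section = dict(cfg.get("cost_inputs") or {})
    if "tariff_params" in section:
        section["tariff_params"] = {
            mode: TariffParams(**params)
            for mode, params in section["tariff_params"].items()
        }
    return _apply(CostInputs(), section, "cost_inputs")


def build_scenario(cfg: dict) -> ScenarioConfig:
    section = dict(cfg.get("scenario") or {})
    if "duration_specs" in section:
        section["duration_specs"] = {
            name: DistributionSpec(spec["family"], tuple(spec["params"]))
            for name, spec in section["duration_specs"].items()
        }
    return _apply(ScenarioConfig(), section, "scenario")


def build_experiment_plan(cfg: dict, scenario: ScenarioConfig | None = None) -> ExperimentPlan:
    section = dict(cfg.get("experiment") or {})
    step = section.pop("grid_step", None)
    plan = ExperimentPlan(scenario_template=scenario or build_scenario(cfg))
    if step is not None and "probability_grid" not in section:
        section["probability_grid"] = build_grid(float(step))
    if "probability_grid" in section:
        section["probability_grid"] = [tuple(t) for t in section["probability_grid"]]
    return _apply(plan, section, "experiment")


def validate_config(cfg: dict) -> list[str]:
    """Check every section's invariants; return findings (empty = valid)."""
    findings: list[str] = []

    def _try(builder, validator, path):
        try:
            obj = builder(cfg)
            if validator:
                validator(obj)
        except (ConfigurationError, CostModelError, SimulationError, TypeError) as exc:
            findings.append(f"{path}: {exc}")

    _try(build_population_params, lambda o: o.validate(), "population")
    _try(build_cost_inputs, lambda o: o.validate(), "cost_inputs")
    _try(build_scenario, lambda o: o.validate(), "scenario")
    if cfg.get("experiment"):
        _try(lambda c: build_experiment_plan(c), lambda o: o.validate(), "experiment")
    return findings
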