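"""Scenario sweeps, average-cost curves and break-even analysis.

The sweeps explore deployment strategies for teleconsultation by varying
the pathway probability triple (P_CS, P_video, P_station) over a simplex
lattice (experiment 1), restricting the population to elderly nursing-home
residents who are always medically transported (experiment 2), or
stratifying the population by one-way distance to the hospital — urban
(<20 km), peri-urban (20-50 km) and remote (>=50 km) (experiment 3).

Break-even analysis asks at what teleconsultation volume the average cost
per TC — fixed investment spread over the volume, plus the per-consultation
variable cost — falls to the average cost of a physical consultation:

    volume* = ceil(fixed / (reference_cs_cost - variable_cost))

Per-day rates convert the horizon volume to daily throughput at one-decimal
rounding. A non-positive margin means the equipment can never be amortized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .costs import CostInputs
from .des import (
    KPIReport,
    ScenarioConfig,
    SimulationError,
    WORKING_DAYS_PER_YEAR,
    fixed_costs_for_horizon,
    run_replication,
)

__all__ = [
    "ExperimentPlan",
    "BreakEvenResult",
    "build_grid",
    "exp2_grid",
    "run_experiment",
    "average_cost_curve",
    "break_even",
    "stratified_break_even",
    "DISTANCE_STRATA",
]

# one-way km strata mirroring the urban / peri-urban / remote split
DISTANCE_STRATA: dict[str, tuple[float, float]] = {
    "urban": (0.0, 20.0),
    "peri_urban": (20.0, 50.0),
    "remote": (50.0, math.inf),
}


@dataclass
class ExperimentPlan:
    """A sweep: one scenario template instantiated at each probability triple."""

    experiment_id: str = "exp1"
    probability_grid: list[tuple[float, float, float]] = field(default_factory=list)
    scenario_template: ScenarioConfig = field(default_factory=ScenarioConfig)
    replications: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not self.probability_grid:
            raise SimulationError("probability grid is empty")
        for triple in self.probability_grid:
            if abs(sum(triple) - 1.0) > 1e-9 or min(triple) < -1e-12:
                raise SimulationError(f"invalid probability triple {triple}")
        if self.replications < 1:
            raise SimulationError("replications must be at least 1")


def build_grid(step: float) -> list[tuple[float, float, float]]:
    """All non-negative probability triples on the step lattice summing to 1."""
    if step <= 0 or step > 1:
        raise SimulationError("step must lie in (0, 1]")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise SimulationError("step must divide 1 exactly")
    out = []
    for i in range(m + 1):
        for j in range(m - i + 1):
            k = m - i - j
            out.append((i / m, j / m, k / m))
    return out


def exp2_grid(step: float = 0.01) -> list[tuple[float, float, float]]:
    """No-video grid: (P_CS, 0, 1 - P_CS) with P_CS swept from 0 to 1."""
    if step <= 0 or step > 1:
        raise SimulationError("step must lie in (0, 1]")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise SimulationError("step must divide 1 exactly")
    return [(i / m, 0.0, (m - i) / m) for i in range(m + 1)]


def run_experiment(
    plan: ExperimentPlan, population: pd.DataFrame, inputs: CostInputs
) -> pd.DataFrame:
    """Run every scenario of the plan; one row per scenario x replication.

    Per-scenario, per-replication seeds are spawned deterministically from
    the plan seed, so two plans differing only in their seed run identical
    scenario lists with different draws.
    """
    plan.validate()
    rows = []
    # common random numbers: replication r uses the same seed in every
    # scenario, so scenario comparisons are paired on identical agent streams
    rep_seeds = [
        int(np.random.default_rng(ss).integers(0, 2**31 - 1))
        for ss in np.random.SeedSequence(plan.seed).spawn(plan.replications)
    ]
    for s_idx, triple in enumerate(plan.probability_grid):
        scenario = replace(
            plan.scenario_template,
            p_cs=triple[0],
            p_visio=triple[1],
            p_station=triple[2],
            replications=plan.replications,
        )
        for r_idx, seed in enumerate(rep_seeds):
            report = run_replication(scenario, population, inputs, seed)
            row = {
                "experiment_id": plan.experiment_id,
                "scenario_index": s_idx,
                "p_cs": triple[0],
                "p_visio": triple[1],
                "p_station": triple[2],
                "replication": r_idx,
            }
            row.update(report.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def average_cost_curve(
    volumes: Sequence[float], fixed_costs: float, variable_cost: float
) -> np.ndarray:
    """Average cost per consultation at each volume: fixed/v + variable.

    Strictly decreasing and convex in volume whenever fixed_costs > 0.
    """
    v = np.asarray(volumes, dtype=float)
    if (v <= 0).any():
        raise SimulationError("volumes must be positive (average cost undefined at 0)")
    if fixed_costs < 0 or variable_cost < 0:
        raise SimulationError("costs must be non-negative")
    return fixed_costs / v + variable_cost


@dataclass
class BreakEvenResult:
    """Minimum TC volumes/rates at which average TC cost meets CS cost."""

    video_breakeven_volume: float
    station_breakeven_volume: float
    per_day_video: float
    per_day_fleet: float
    per_day_per_station: float
    reference_cs_cost: float
    amortizable_video: bool = True
    amortizable_station: bool = True


def _breakeven_volume(fixed: float, margin: float) -> tuple[float, bool]:
    if fixed == 0:
        return 0.0, True
    if margin <= 0:
        return math.inf, False
    return float(math.ceil(fixed / margin)), True


def break_even(
    fixed_video: float,
    fixed_station: float,
    reference_cs_cost: float,
    variable_video: float,
    variable_station: float,
    working_days: int = 5 * WORKING_DAYS_PER_YEAR,
    n_stations: int = 12,
) -> BreakEvenResult:
    """Closed-form break-even volumes and per-day rates (one-decimal)."""
    vol_v, ok_v = _breakeven_volume(fixed_video, reference_cs_cost - variable_video)
    vol_s, ok_s = _breakeven_volume(fixed_station, reference_cs_cost - variable_station)
    per_day = lambda v: round(v / working_days, 1) if math.isfinite(v) else math.inf
    return BreakEvenResult(
        video_breakeven_volume=vol_v,
        station_breakeven_volume=vol_s,
        per_day_video=per_day(vol_v),
        per_day_fleet=per_day(vol_s),
        per_day_per_station=(
            round(vol_s / (working_days * n_stations), 1)
            if math.isfinite(vol_s)
            else math.inf
        ),
        reference_cs_cost=reference_cs_cost,
        amortizable_video=ok_v,
        amortizable_station=ok_s,
    )


def _simulated_break_even(
    scenario: ScenarioConfig, population: pd.DataFrame, inputs: CostInputs
) -> BreakEvenResult:
    """Break-even from simulated per-type cost components.

    Runs the scenario replications, takes the mean variable cost per
    completed consultation of each type as the reference/variable costs,
    and plugs the horizon fixed costs into the closed form.
    """
    seeds = [
        int(np.random.default_rng(ss).integers(0, 2**31 - 1))
        for ss in np.random.SeedSequence(scenario.seed).spawn(scenario.replications)
    ]
    reports = [run_replication(scenario, population, inputs, s) for s in seeds]
    tot = lambda attr: sum(getattr(r, attr) for r in reports)
    n_cs, n_video, n_station = tot("n_cs"), tot("n_video"), tot("n_station")
    if n_cs == 0:
        raise SimulationError("no completed CS consultations; cannot set reference cost")
    ref_cs = tot("variable_cost_cs") / n_cs
    var_video = (tot("variable_cost_video") / n_video) if n_video else inputs.consult_fee
    var_station = (
        tot("variable_cost_station") / n_station
        if n_station
        else inputs.consult_fee + inputs.nurse_fee
    )
    fixed_video, fixed_station = fixed_costs_for_horizon(inputs, scenario.horizon_months)
    return break_even(
        fixed_video,
        fixed_station,
        ref_cs,
        var_video,
        var_station,
        working_days=scenario.horizon_days,
        n_stations=scenario.n_stations,
    )


def stratified_break_even(
    population: pd.DataFrame,
    inputs: CostInputs,
    scenario_template: ScenarioConfig,
    strata: dict[str, Callable[[pd.DataFrame], np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Per-stratum break-even table.

    ``strata`` maps labels to boolean predicates over the population frame;
    defaults to the urban / peri-urban / remote one-way distance split.
    Empty strata are flagged rather than raising.
    """
    if strata is None:
        strata = {
            label: (lambda df, lo=lo, hi=hi: (df.distance_km >= lo) & (df.distance_km < hi))
            for label, (lo, hi) in DISTANCE_STRATA.items()
        }
    rows = []
    for label, pred in strata.items():
        mask = np.asarray(pred(population), dtype=bool)
        if not mask.any():
            rows.append({"stratum": label, "empty": True})
            continue
        scenario = replace(scenario_template, population_filter=pred)
        be = _simulated_break_even(scenario, population, inputs)
        rows.append(
            {
                "stratum": label,
                "empty": False,
                "n_patients": int(mask.sum()),
                "reference_cs_cost": be.reference_cs_cost,
                "video_breakeven_volume": be.video_breakeven_volume,
                "station_breakeven_volume": be.station_breakeven_volume,
                "per_day_video": be.per_day_video,
                "per_day_fleet": be.per_day_fleet,
                "per_day_per_station": be.per_day_per_station,
                "amortizable_video": be.amortizable_video,
                "amortizable_station": be.amortizable_station,
            }
        )
    return pd.DataFrame(rows)
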