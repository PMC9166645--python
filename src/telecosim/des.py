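"""Day-stepped discrete-event simulation of three consultation pathways.

The simulated system offers each arriving consultation request one of three
routes:

* **CS** — a physical consultation at the hospital: the patient makes a
  round trip, a doctor consultation (triangular service time) and
  background administrative scheduling take place;
* **video TC** — a remote consultation via videoconferencing: shorter
  doctor time, no travel, extra admin/registration work for new patients,
  and a probability that a physical follow-up consultation is needed within
  a week (the agent is then also processed as a CS and counted as a
  transfer);
* **station TC** — a remote consultation via a telehealth station operated
  with a nurse: no patient travel, nurse preparation/closing times around a
  shifted-lognormal doctor consultation. Each station handles at most
  ``station_daily_capacity`` consultations per day and the accompanying
  nurse may be on sick leave; in either case the agent is redirected to a
  same-day CS and counted as a transfer.

Agents older than 80 years are assumed less able to use videoconferencing:
their video probability is capped at 0.3, the excess reallocated equally to
the other two routes. Patients whose diagnosis chapter or care unit was
never observed in the TC group are ineligible for either TC route and
always take the CS pathway.

Days are the scheduling unit (arrivals per day are Poisson; station quotas
reset daily; within-day order is arrival order). There is no waiting-time
KPI, so sub-day interleaving is immaterial; one day counts as 1440 minutes
for horizon arithmetic (the 5-year study horizon of 1265 working days is
1,821,600 minutes). Doctor, administrative and nurse resources are
uncapacitated accumulators whose consumption is tracked in minutes.

Randomness is organised as independent named substreams spawned from one
root seed per replication, so adding an indicator never perturbs existing
draws and every run is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .costs import (
    CostInputs,
    medical_transport_cost,
    monthly_equipment_device,
    monthly_equipment_wallet,
    nonmedical_transport_cost,
)
from .population import TABLE_COUNTS, sample_agents

__all__ = [
    "DistributionSpec",
    "ScenarioConfig",
    "KPIReport",
    "SimulationError",
    "canonicalize_triangular",
    "default_duration_specs",
    "default_eligibility",
    "assign_pathway",
    "process_agent",
    "run_replication",
    "summarize_replications",
    "fixed_costs_for_horizon",
    "WORKING_DAYS_PER_YEAR",
    "MINUTES_PER_DAY",
]

WORKING_DAYS_PER_YEAR = 253
MINUTES_PER_DAY = 1440


class SimulationError(ValueError):
    pass


def canonicalize_triangular(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Sort three triangular parameters into (min, mode, max).

    Source parameter tables mix (min, max, mode) and (min, mode, max)
    orderings; sorting resolves both, since the mode of a triangular law
    always lies between its bounds.
    """
    vals = sorted((float(a), float(b), float(c)))
    if any(not math.isfinite(v) or v < 0 for v in vals):
        raise SimulationError("triangular parameters must be finite and non-negative")
    return (vals[0], vals[1], vals[2])


@dataclass(frozen=True)
class DistributionSpec:
    """A service-time or count distribution, in minutes unless noted.

    Families: ``triangular`` (three values, canonicalized to
    min <= mode <= max), ``lognormal3`` (log-mean, log-sd, location shift),
    ``poisson`` (rate), ``bernoulli`` (success probability), ``constant``.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        fam = self.family
        p = self.params
        if fam == "triangular":
            if len(p) != 3:
                raise SimulationError("triangular needs three parameters")
            object.__setattr__(self, "params", canonicalize_triangular(*p))
        elif fam == "lognormal3":
            if len(p) != 3 or p[1] <= 0:
                raise SimulationError("lognormal3 needs (log-mean, log-sd>0, shift)")
        elif fam == "poisson":
            if len(p) != 1 or p[0] <= 0:
                raise SimulationError("poisson needs a positive rate")
        elif fam == "bernoulli":
            if len(p) != 1 or not 0 <= p[0] <= 1:
                raise SimulationError("bernoulli needs a probability")
        elif fam == "constant":
            if len(p) != 1:
                raise SimulationError("constant needs one value")
        else:
            raise SimulationError(f"unknown distribution family {fam!r}")

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "triangular":
            lo, mode, hi = p
            if lo == hi:
                return lo
            return float(rng.triangular(lo, mode, hi))
        if self.family == "lognormal3":
            mu, sigma, shift = p
            return shift + float(rng.lognormal(mu, sigma))
        if self.family == "poisson":
            return float(rng.poisson(p[0]))
        if self.family == "bernoulli":
            return float(rng.uniform() < p[0])
        return p[0]

    def mean(self) -> float:
        p = self.params
        if self.family == "triangular":
            return sum(p) / 3.0
        if self.family == "lognormal3":
            mu, sigma, shift = p
            return shift + math.exp(mu + sigma**2 / 2.0)
        return p[0]


def default_duration_specs() -> dict[str, DistributionSpec]:
    tri = lambda a, b, c: DistributionSpec("triangular", (a, b, c))
    return {
        "cs_admin": tri(1, 2, 1.5),
        "cs_doctor": tri(16.9, 29.1, 20),
        "video_doctor": tri(8, 9.47, 13.78),
        "video_admin": tri(1, 2, 1.5),
        "video_admin_new": tri(8, 10, 9),
        "video_registration": tri(1, 2, 1.5),
        "station_nurse_prep": tri(8, 12, 10),
        "station_doctor": DistributionSpec(
            "lognormal3", (2.1888426, 0.57548749, 3.0333333)
        ),
        "station_nurse_close": tri(3, 7, 5),
        "station_admin": tri(2.5, 4.5, 3.5),
        "station_admin_new": tri(10, 15, 12.5),
    }


def default_eligibility(agents: pd.DataFrame) -> np.ndarray:
    """TC eligibility: diagnosis chapter and care unit ever observed for TC
    patients in the calibration cohort."""
    ok_icd = {c for c, (tc, _) in TABLE_COUNTS["icd10_chapter"].items() if tc > 0}
    ok_unit = {c for c, (tc, _) in TABLE_COUNTS["care_unit"].items() if tc > 0}
    return (
        agents["icd10_chapter"].isin(ok_icd) & agents["care_unit"].isin(ok_unit)
    ).to_numpy()


@dataclass
class ScenarioConfig:
    """One simulated deployment scenario.

    Defaults are the base (validation) conditions observed in the 2020
    clinical data: pathway probabilities (0.9507, 0.0362, 0.0131), Poisson
    daily arrival rate 89.953782, 12 telehealth stations with a 7-per-day
    capacity each, a 5-year horizon of 1265 working days, 20 replications.
    """

    p_cs: float = 0.9507
    p_visio: float = 0.0362
    p_station: float = 0.0131
    arrival_rate: float = 89.953782
    n_stations: int = 12
    teams_per_station: int = 1
    station_daily_capacity: int = 7
    share_med_transport: float = 0.36
    population_filter: Callable[[pd.DataFrame], np.ndarray] | None = None
    fixed_distance_km: float | None = None
    horizon_days: int = 5 * WORKING_DAYS_PER_YEAR
    minutes_per_day: int = MINUTES_PER_DAY
    replications: int = 20
    seed: int = 0
    duration_specs: dict[str, DistributionSpec] = field(
        default_factory=default_duration_specs
    )
    eligibility: Callable[[pd.DataFrame], np.ndarray] | None = None
    p_first_tc_patient: float = 0.2368
    p_first_tc: float = 0.8512
    p_cs_after_video: float = 0.0672
    p_nurse_sick_base: float = 0.05
    video_age_limit: float = 80.0
    p_visio_cap: float = 0.3

    def validate(self) -> None:
        if abs(self.p_cs + self.p_visio + self.p_station - 1.0) > 1e-9:
            raise SimulationError("pathway probabilities must sum to 1")
        if min(self.p_cs, self.p_visio, self.p_station) < 0:
            raise SimulationError("pathway probabilities must be non-negative")
        if self.horizon_days <= 0:
            raise SimulationError("horizon_days must be positive")
        if self.arrival_rate <= 0:
            raise SimulationError("arrival_rate must be positive")
        missing = set(default_duration_specs()) - set(self.duration_specs)
        if missing:
            raise SimulationError(f"duration_specs missing activities: {sorted(missing)}")

    @property
    def horizon_minutes(self) -> int:
        return self.horizon_days * self.minutes_per_day

    @property
    def horizon_months(self) -> float:
        return self.horizon_days / WORKING_DAYS_PER_YEAR * 12.0

    @property
    def p_new_patient(self) -> float:
        # consult-level probability that the agent is new to teleconsultation
        return self.p_first_tc_patient * self.p_first_tc

    @property
    def p_nurse_sick(self) -> float:
        return self.p_nurse_sick_base / max(self.teams_per_station, 1)


@dataclass
class KPIReport:
    """Per-replication key performance indicators."""

    total_cost: float
    cost_per_cs: float
    cost_per_video: float
    cost_per_station: float
    doctor_minutes: float
    admin_minutes: float
    nurse_minutes: float
    n_transfers: int
    n_cs: int
    n_video: int
    n_station: int
    n_arrivals: int
    n_assigned_cs: int
    n_assigned_video: int
    n_assigned_station: int
    total_travel_minutes: float
    travel_minutes_avoided: float
    variable_cost_cs: float
    variable_cost_video: float
    variable_cost_station: float
    fixed_cost_video: float
    fixed_cost_station: float
    max_station_daily: int
    horizon_days: int
    seed: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def assign_pathway(age: float, eligible: bool, scenario: ScenarioConfig, rng) -> str:
    """Draw a pathway for one agent.

    Ineligible agents always take the CS pathway. For agents above the video
    age limit, the video probability is capped; the excess is reallocated
    equally to the CS and station routes.
    """
    if not eligible:
        return "cs"
    p_cs, p_v, p_s = scenario.p_cs, scenario.p_visio, scenario.p_station
    if age > scenario.video_age_limit and p_v > scenario.p_visio_cap:
        excess = p_v - scenario.p_visio_cap
        p_cs, p_v, p_s = p_cs + excess / 2.0, scenario.p_visio_cap, p_s + excess / 2.0
    u = rng.uniform()
    if u < p_cs:
        return "cs"
    if u < p_cs + p_v:
        return "video"
    return "station"


class _AgentView:
    """Minimal agent attribute carrier used in the hot replication loop."""

    __slots__ = ("travel_time_min", "distance_km")

    def __init__(self, travel_time_min: float, distance_km: float):
        self.travel_time_min = travel_time_min
        self.distance_km = distance_km


class _StationFleet:
    """Daily quota bookkeeping: load-balances agents onto the station with
    the fewest completed consultations today, subject to the per-day cap."""

    def __init__(self, n_stations: int, capacity: int):
        self.capacity = capacity
        self.counts = np.zeros(max(n_stations, 0), dtype=int)
        self.max_daily = 0

    def new_day(self):
        if len(self.counts) and self.counts.max() > self.max_daily:
            self.max_daily = int(self.counts.max())
        self.counts[:] = 0

    def try_book(self) -> int | None:
        if len(self.counts) == 0:
            return None
        j = int(np.argmin(self.counts))
        if self.counts[j] >= self.capacity:
            return None
        self.counts[j] += 1
        return j


def process_agent(
    agent,
    pathway: str,
    scenario: ScenarioConfig,
    streams: dict[str, np.random.Generator],
    fleet: _StationFleet | None = None,
) -> dict:
    """Process one agent along its assigned pathway.

    Returns an event record with sampled durations (minutes), travel,
    transfer flag and the completed consultation types. ``streams`` maps
    substream names (``durations``, ``transfer``, ``nurse_sick``,
    ``new_patient``) to generators; a single generator may be passed for all.
    """
    if isinstance(streams, np.random.Generator):
        g = streams
        streams = {k: g for k in ("durations", "transfer", "nurse_sick", "new_patient")}
    spec = scenario.duration_specs
    dur = streams["durations"]
    travel_min = (
        float(agent.travel_time_min)
        if scenario.fixed_distance_km is None
        else scenario.fixed_distance_km / 0.9
    )
    distance_km = (
        float(agent.distance_km)
        if scenario.fixed_distance_km is None
        else scenario.fixed_distance_km
    )
    rec = {
        "pathway": pathway,
        "distance_km": distance_km,
        "doctor_min": 0.0,
        "admin_min": 0.0,
        "nurse_min": 0.0,
        "travel_min": 0.0,
        "travel_avoided_min": 0.0,
        "transfer": False,
        "completed_cs": 0,
        "completed_video": 0,
        "completed_station": 0,
        "station_id": None,
    }

    def do_cs():
        rec["doctor_min"] += spec["cs_doctor"].sample(dur)
        rec["admin_min"] += spec["cs_admin"].sample(dur)
        rec["travel_min"] += 2.0 * travel_min
        rec["completed_cs"] += 1

    if pathway == "cs":
        do_cs()
    elif pathway == "video":
        new = streams["new_patient"].uniform() < scenario.p_new_patient
        rec["doctor_min"] += spec["video_doctor"].sample(dur)
        rec["admin_min"] += spec[
            "video_admin_new" if new else "video_admin"
        ].sample(dur)
        if streams["new_patient"].uniform() < scenario.p_first_tc:
            rec["doctor_min"] += spec["video_registration"].sample(dur)
        rec["completed_video"] += 1
        if streams["transfer"].uniform() < scenario.p_cs_after_video:
            rec["transfer"] = True
            do_cs()
    elif pathway == "station":
        sick = streams["nurse_sick"].uniform() < scenario.p_nurse_sick
        slot = None if sick or fleet is None else fleet.try_book()
        if sick or slot is None:
            rec["transfer"] = True
            do_cs()
        else:
            new = streams["new_patient"].uniform() < scenario.p_new_patient
            rec["station_id"] = slot
            rec["nurse_min"] += spec["station_nurse_prep"].sample(dur)
            rec["doctor_min"] += spec["station_doctor"].sample(dur)
            rec["nurse_min"] += spec["station_nurse_close"].sample(dur)
            rec["admin_min"] += spec[
                "station_admin_new" if new else "station_admin"
            ].sample(dur)
            rec["completed_station"] += 1
    else:
        raise SimulationError(f"unknown pathway {pathway!r}")

    rec["travel_avoided_min"] = max(0.0, 2.0 * travel_min - rec["travel_min"])
    return rec


def fixed_costs_for_horizon(
    inputs: CostInputs, horizon_months: float
) -> tuple[float, float]:
    """(video, station) fixed equipment cost over a simulation horizon.

    Monthly-amortized items accrue for ``horizon_months``; one-off items
    (headsets, medical device kits) are charged once. Over a 60-month
    horizon this equals the full five-year investment.
    """
    video = (
        inputs.n_doctors * inputs.software_monthly_per_user * horizon_months
        + inputs.n_doctors * inputs.headphone_per_user
    )
    n_equipped = (
        inputs.n_full_stations
        if inputs.med_equipment_full_stations_only
        else inputs.n_stations
    )
    station = (
        inputs.n_full_stations * monthly_equipment_device(inputs)
        + inputs.n_wallet_stations * monthly_equipment_wallet(inputs)
        + inputs.n_stations * inputs.maintenance_monthly
    ) * horizon_months + n_equipped * inputs.med_equipment_per_station
    return float(video), float(station)


def _travel_cost(distance_km_round: float, inputs: CostInputs, share_med: float) -> float:
    if distance_km_round <= 0:
        return 0.0
    return share_med * medical_transport_cost(
        distance_km_round, inputs
    ) + (1.0 - share_med) * nonmedical_transport_cost(distance_km_round, inputs)


def run_replication(
    scenario: ScenarioConfig,
    population: pd.DataFrame,
    inputs: CostInputs,
    seed: int,
    collect_events: bool = False,
) -> KPIReport | tuple[KPIReport, list[dict]]:
    """Simulate one replication over the scenario horizon.

    Arrivals are Poisson per day; agent attributes are resampled with
    replacement from the (filtered) population; station quotas reset daily.
    Per-agent variable costs use the cost model with the scenario's
    transport share; fixed equipment costs are charged once per replication,
    pro-rata to the horizon, and only for technologies with at least one
    completed consultation (no use, no investment, no fixed cost).
    """
    scenario.validate()
    root = np.random.SeedSequence(seed)
    names = ("arrivals", "pathway", "durations", "transfer", "nurse_sick", "new_patient")
    streams = {
        name: np.random.default_rng(ss) for name, ss in zip(names, root.spawn(len(names)))
    }

    agents = sample_agents(
        population,
        scenario.horizon_days,
        scenario.arrival_rate,
        seed=int(streams["arrivals"].integers(0, 2**31 - 1)),
        population_filter=scenario.population_filter,
    )
    elig_fn = scenario.eligibility or default_eligibility
    eligible = np.asarray(elig_fn(agents), dtype=bool)

    fleet = _StationFleet(scenario.n_stations, scenario.station_daily_capacity)
    days = agents["day"].to_numpy()
    ages = agents["age"].to_numpy()
    tts = agents["travel_time_min"].to_numpy(dtype=float)
    dks = agents["distance_km"].to_numpy(dtype=float)

    doctor = admin = nurse = 0.0
    travel = avoided = 0.0
    n_cs = n_video = n_station = n_transfers = 0
    assigned = {"cs": 0, "video": 0, "station": 0}
    var_cs = var_video = var_station = 0.0
    events: list[dict] = []

    current_day = -1
    g_path = streams["pathway"]
    for i in range(len(agents)):
        if days[i] != current_day:
            fleet.new_day()
            current_day = days[i]
        pathway = assign_pathway(ages[i], bool(eligible[i]), scenario, g_path)
        assigned[pathway] += 1
        rec = process_agent(_AgentView(tts[i], dks[i]), pathway, scenario, streams, fleet)
        doctor += rec["doctor_min"]
        admin += rec["admin_min"]
        nurse += rec["nurse_min"]
        travel += rec["travel_min"]
        avoided += rec["travel_avoided_min"]
        n_cs += rec["completed_cs"]
        n_video += rec["completed_video"]
        n_station += rec["completed_station"]
        n_transfers += int(rec["transfer"])
        # variable cost per completed consultation
        if rec["completed_cs"]:
            var_cs += rec["completed_cs"] * inputs.consult_fee + _travel_cost(
                2.0 * rec["distance_km"] * rec["completed_cs"],
                inputs,
                scenario.share_med_transport,
            )
        if rec["completed_video"]:
            var_video += rec["completed_video"] * inputs.consult_fee
        if rec["completed_station"]:
            var_station += rec["completed_station"] * (
                inputs.consult_fee + inputs.nurse_fee
            )
        if collect_events:
            rec["day"] = int(days[i])
            events.append(rec)
    fleet.new_day()  # flush the last day into the quota audit

    fixed_video_full, fixed_station_full = fixed_costs_for_horizon(
        inputs, scenario.horizon_months
    )
    # investment is charged only for technologies actually used (the elderly
    # video cap can route agents to stations even when p_station is 0)
    fixed_video = fixed_video_full if n_video > 0 else 0.0
    fixed_station = fixed_station_full if n_station > 0 else 0.0

    report = KPIReport(
        total_cost=var_cs + var_video + var_station + fixed_video + fixed_station,
        cost_per_cs=(var_cs / n_cs) if n_cs else float("nan"),
        cost_per_video=((var_video + fixed_video) / n_video) if n_video else float("nan"),
        cost_per_station=(
            (var_station + fixed_station) / n_station if n_station else float("nan")
        ),
        doctor_minutes=doctor,
        admin_minutes=admin,
        nurse_minutes=nurse,
        n_transfers=n_transfers,
        n_cs=n_cs,
        n_video=n_video,
        n_station=n_station,
        n_arrivals=len(agents),
        n_assigned_cs=assigned["cs"],
        n_assigned_video=assigned["video"],
        n_assigned_station=assigned["station"],
        total_travel_minutes=travel,
        travel_minutes_avoided=avoided,
        variable_cost_cs=var_cs,
        variable_cost_video=var_video,
        variable_cost_station=var_station,
        fixed_cost_video=fixed_video,
        fixed_cost_station=fixed_station,
        max_station_daily=fleet.max_daily,
        horizon_days=scenario.horizon_days,
        seed=seed,
    )
    if collect_events:
        return report, events
    return report


def run_scenario(
    scenario: ScenarioConfig, population: pd.DataFrame, inputs: CostInputs
) -> list[KPIReport]:
    """Run all replications of a scenario with spawned per-replication seeds."""
    seeds = [
        int(np.random.default_rng(ss).integers(0, 2**31 - 1))
        for ss in np.random.SeedSequence(scenario.seed).spawn(scenario.replications)
    ]
    return [run_replication(scenario, population, inputs, s) for s in seeds]


def summarize_replications(reports: list[KPIReport]) -> pd.DataFrame:
    """Across-replication mean and t-based 95% half-width per KPI."""
    if len(reports) < 2:
        raise SimulationError("need at least 2 replications to summarize")
    from scipy import stats

    df = pd.DataFrame([r.as_dict() for r in reports])
    num = df.select_dtypes("number").drop(columns=["seed"], errors="ignore")
    n = len(df)
    tcrit = stats.t.ppf(0.975, n - 1)
    out = pd.DataFrame(
        {
            "mean": num.mean(),
            "half_width_95": tcrit * num.std(ddof=1) / np.sqrt(n),
        }
    )
    return out
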