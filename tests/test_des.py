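"""Discrete-event simulation: distributions, pathways, replications."""

import math
from dataclasses import replace

import numpy as np
import pytest

from telecosim.costs import CostInputs
from telecosim.des import (
    DistributionSpec,
    ScenarioConfig,
    SimulationError,
    assign_pathway,
    canonicalize_triangular,
    default_duration_specs,
    fixed_costs_for_horizon,
    process_agent,
    run_replication,
    summarize_replications,
    _StationFleet,
)


class _FixedUniform:
    """Deterministic stand-in generator yielding preset uniforms."""

    def __init__(self, values):
        self._values = list(values)

    def uniform(self, *a, **k):
        return self._values.pop(0)


class TestDistributions:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ((16.9, 29.1, 20), (16.9, 20, 29.1)),
            ((8, 9.47, 13.78), (8, 9.47, 13.78)),
            ((5, 5, 5), (5, 5, 5)),
        ],
    )
    def test_triangular_canonicalization(self, raw, expected):
        assert canonicalize_triangular(*raw) == pytest.approx(expected)

    def test_triangular_rejects_negative(self):
        with pytest.raises(SimulationError):
            canonicalize_triangular(-1, 2, 3)

    def test_degenerate_triangular_is_constant(self):
        spec = DistributionSpec("triangular", (5, 5, 5))
        rng = np.random.default_rng(0)
        assert all(spec.sample(rng) == 5 for _ in range(10))

    def test_station_consult_time_closed_form_mean(self):
        """Sample mean of the shifted lognormal matches shift+exp(mu+s^2/2)."""
        spec = default_duration_specs()["station_doctor"]
        rng = np.random.default_rng(123)
        draws = np.array([spec.sample(rng) for _ in range(100_000)])
        mu, sigma, shift = 2.1888426, 0.57548749, 3.0333333
        expected = shift + math.exp(mu + sigma**2 / 2)
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 2 * se
        assert (draws >= shift).all()

    @pytest.mark.parametrize(
        "family,params",
        [("lognormal3", (1.0, -0.5, 0.0)), ("poisson", (-2,)), ("bernoulli", (1.4,)),
         ("nope", (1,))],
    )
    def test_invalid_specs_rejected(self, family, params):
        with pytest.raises(SimulationError):
            DistributionSpec(family, params)

    def test_all_sampled_durations_nonnegative(self):
        rng = np.random.default_rng(9)
        for spec in default_duration_specs().values():
            assert min(spec.sample(rng) for _ in range(500)) >= 0


class TestPathwayAssignment:
    def test_elderly_video_cap_redistribution(self):
        """Age > 80 with p_visio = 0.5 yields effective (0.4, 0.3, 0.3)."""
        sc = ScenarioConfig(p_cs=0.3, p_visio=0.5, p_station=0.2)
        # thresholds under the redistributed (0.4, 0.3, 0.3)
        assert assign_pathway(85, True, sc, _FixedUniform([0.39])) == "cs"
        assert assign_pathway(85, True, sc, _FixedUniform([0.41])) == "video"
        assert assign_pathway(85, True, sc, _FixedUniform([0.69])) == "video"
        assert assign_pathway(85, True, sc, _FixedUniform([0.71])) == "station"
        # a younger agent keeps the raw probabilities
        assert assign_pathway(50, True, sc, _FixedUniform([0.35])) == "video"

    def test_pure_cs_certain(self):
        sc = ScenarioConfig(p_cs=1.0, p_visio=0.0, p_station=0.0)
        rng = np.random.default_rng(0)
        assert all(assign_pathway(a, True, sc, rng) == "cs" for a in (30, 90))

    def test_ineligible_always_cs(self):
        sc = ScenarioConfig(p_cs=0.0, p_visio=1.0, p_station=0.0)
        rng = np.random.default_rng(0)
        assert assign_pathway(40, False, sc, rng) == "cs"

    def test_base_probabilities_unchanged_for_young(self):
        sc = ScenarioConfig()  # base (0.9507, 0.0362, 0.0131), cap inactive
        rng = np.random.default_rng(1)
        draws = [assign_pathway(50, True, sc, rng) for _ in range(20_000)]
        frac_cs = draws.count("cs") / len(draws)
        assert abs(frac_cs - 0.9507) < 3 * math.sqrt(0.9507 * 0.0493 / 20_000)


class _Agent:
    travel_time_min = 30.0
    distance_km = 27.0


class TestProcessAgent:
    def test_station_quota_exhausted_redirects_with_travel(self):
        sc = ScenarioConfig(p_cs=0.0, p_visio=0.0, p_station=1.0, p_nurse_sick_base=0.0)
        fleet = _StationFleet(n_stations=1, capacity=7)
        for _ in range(7):
            fleet.try_book()
        rng = np.random.default_rng(0)
        rec = process_agent(_Agent(), "station", sc, rng, fleet)
        assert rec["transfer"] and rec["completed_cs"] == 1
        assert rec["completed_station"] == 0
        assert rec["travel_min"] == pytest.approx(60.0)
        assert rec["travel_avoided_min"] == 0.0

    def test_video_without_transfer_has_no_travel(self):
        sc = ScenarioConfig(p_cs=0.0, p_visio=1.0, p_station=0.0, p_cs_after_video=0.0)
        rng = np.random.default_rng(0)
        rec = process_agent(_Agent(), "video", sc, rng)
        assert rec["travel_min"] == 0.0
        assert rec["travel_avoided_min"] == pytest.approx(60.0)
        assert not rec["transfer"]

    def test_nurse_sick_redirects(self):
        sc = replace(ScenarioConfig(), p_nurse_sick_base=1.0, teams_per_station=1)
        fleet = _StationFleet(1, 7)
        rec = process_agent(_Agent(), "station", sc, np.random.default_rng(0), fleet)
        assert rec["transfer"] and rec["completed_cs"] == 1

    def test_unknown_pathway_rejected(self):
        with pytest.raises(SimulationError):
            process_agent(_Agent(), "teleport", ScenarioConfig(), np.random.default_rng(0))


class TestReplication:
    def test_pure_cs_scenario(self, small_population, cost_inputs):
        sc = ScenarioConfig(
            p_cs=1.0, p_visio=0.0, p_station=0.0, horizon_days=20, arrival_rate=20
        )
        r = run_replication(sc, small_population, cost_inputs, seed=1)
        assert r.n_transfers == 0
        assert r.nurse_minutes == 0.0
        assert r.travel_minutes_avoided == 0.0
        assert r.fixed_cost_video == 0.0 and r.fixed_cost_station == 0.0
        assert r.n_video == r.n_station == 0

    def test_volume_conservation_and_event_log(self, small_population, cost_inputs):
        sc = ScenarioConfig(
            p_cs=0.5, p_visio=0.3, p_station=0.2, horizon_days=15, arrival_rate=40,
            n_stations=2,
        )
        r, events = run_replication(
            sc, small_population, cost_inputs, seed=4, collect_events=True
        )
        assert r.n_assigned_cs + r.n_assigned_video + r.n_assigned_station == r.n_arrivals
        assert r.n_cs == r.n_assigned_cs + r.n_transfers
        # event-log replay: resource minutes equal the sum of sampled durations
        assert r.doctor_minutes == pytest.approx(sum(e["doctor_min"] for e in events))
        assert r.admin_minutes == pytest.approx(sum(e["admin_min"] for e in events))
        assert r.nurse_minutes == pytest.approx(sum(e["nurse_min"] for e in events))
        # per-agent travel accounting: travel + avoided = pure-CS counterfactual
        for e in events:
            assert e["travel_min"] + e["travel_avoided_min"] >= 0

    def test_station_daily_quota_respected(self, small_population, cost_inputs):
        sc = ScenarioConfig(
            p_cs=0.0, p_visio=0.0, p_station=1.0, horizon_days=10, arrival_rate=60,
            n_stations=2,
        )
        r = run_replication(sc, small_population, cost_inputs, seed=5)
        assert r.max_station_daily <= 7
        assert r.n_transfers > 0  # 60 eligible arrivals/day >> 14 slots

    def test_deterministic_given_seed(self, small_population, cost_inputs):
        sc = ScenarioConfig(horizon_days=5, arrival_rate=10)
        a = run_replication(sc, small_population, cost_inputs, seed=11)
        b = run_replication(sc, small_population, cost_inputs, seed=11)
        # NaN-tolerant equality (per-type costs are NaN at zero volume)
        import pandas as pd

        assert pd.Series(a.as_dict()).equals(pd.Series(b.as_dict()))

    def test_more_video_means_less_doctor_time(self, small_population, cost_inputs):
        """Video consults are stochastically shorter than physical ones."""
        base = dict(horizon_days=30, arrival_rate=40)
        lo = ScenarioConfig(p_cs=1.0, p_visio=0.0, p_station=0.0, **base)
        hi = ScenarioConfig(p_cs=0.0, p_visio=1.0, p_station=0.0, **base)
        d_lo = run_replication(lo, small_population, cost_inputs, seed=21).doctor_minutes
        d_hi = run_replication(hi, small_population, cost_inputs, seed=21).doctor_minutes
        assert d_hi < d_lo

    def test_base_scenario_tc_share(self, small_population, cost_inputs):
        """Completed TC share is near the base assignment probabilities,
        thinned by eligibility and transfers."""
        sc = ScenarioConfig(horizon_days=60, arrival_rate=89.953782)
        r = run_replication(sc, small_population, cost_inputs, seed=30)
        share = (r.n_video + r.n_station) / (r.n_cs + r.n_video + r.n_station)
        target = 0.0362 + 0.0131
        assert 0.5 * target < share < 1.1 * target

    def test_fixed_costs_match_five_year_totals(self, cost_inputs):
        """Over the 60-month horizon the charged fixed costs equal the full
        five-year investment."""
        video, station = fixed_costs_for_horizon(cost_inputs, 60.0)
        assert video == pytest.approx(30 * 70 * 60 + 30 * 110)
        dep = 6 * (21_686.4 + 1_680 + 1_020) + 6 * (10_200 + 1_020)
        consum = 12 * 360 * 5
        maint = 12 * 90 * 60
        assert station == pytest.approx(dep + consum + maint + 6 * 360)


class TestSummaries:
    def test_identical_reports_zero_half_width(self, small_population, cost_inputs):
        sc = ScenarioConfig(horizon_days=3, arrival_rate=5)
        r = run_replication(sc, small_population, cost_inputs, seed=2)
        summary = summarize_replications([r, r])
        assert (summary.half_width_95.dropna().abs() < 1e-9).all()
        assert summary.loc["total_cost", "mean"] == pytest.approx(r.total_cost)

    def test_two_report_mean(self, small_population, cost_inputs):
        sc = ScenarioConfig(horizon_days=3, arrival_rate=5)
        a = run_replication(sc, small_population, cost_inputs, seed=2)
        b = run_replication(sc, small_population, cost_inputs, seed=3)
        summary = summarize_replications([a, b])
        assert summary.loc["total_cost", "mean"] == pytest.approx(
            (a.total_cost + b.total_cost) / 2
        )

    def test_single_report_rejected(self, small_population, cost_inputs):
        sc = ScenarioConfig(horizon_days=2, arrival_rate=5)
        r = run_replication(sc, small_population, cost_inputs, seed=2)
        with pytest.raises(SimulationError):
            summarize_replications([r])
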