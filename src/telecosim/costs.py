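"""Per-patient cost model for mixed consultation pathways.

The total cost of a patient's care pathway over the follow-up window is the
sum of five components:

* consultation fees — ``NbConsult × consult_fee`` for every physical or
  remote consultation;
* nurse accompaniment — each remote consultation is assumed to have used a
  telehealth station with probability ``p_tc_station``, and station use
  carries a fixed nurse fee, so the expected fee is
  ``p_tc_station × NbTC × nurse_fee``;
* transport — physical visits require a round trip; the cumulative distance
  ``2 × one-way km × physical visits`` is valued as a probability-weighted
  mix of medical transport tariffs (light health vehicle / taxi /
  ambulance, each an affine-with-minimum function of distance) for the
  medically-transported share of patients, and an official cost-per-km rate
  for everyone else. Remote consultations incur no travel;
* equipment — the fixed teleconsultation infrastructure (stations, software
  licences, peripherals) amortized monthly and spread uniformly over the
  observed number of TC patients; control patients carry none of it.

All amounts are euros. Equipment amortization follows straight-line
depreciation: purchase, installation and training costs are spread over
``amortization_months``; maintenance, consumables and software accrue at
their monthly/annual rates; medical device kits and headsets are one-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TariffParams",
    "CostInputs",
    "CostBreakdown",
    "CostModelError",
    "nonmedical_transport_cost",
    "medical_transport_cost",
    "monthly_equipment_device",
    "monthly_equipment_wallet",
    "equipment_cost_per_tc_patient",
    "patient_total_cost",
    "population_costs",
]


class CostModelError(ValueError):
    """Raised on invalid cost inputs or arguments."""


@dataclass(frozen=True)
class TariffParams:
    """Affine-with-minimum transport tariff: max(minimum, base + per_km * d)."""

    base_fare: float
    per_km: float
    minimum: float = 0.0

    def __call__(self, distance_km: float) -> float:
        return max(self.minimum, self.base_fare + self.per_km * distance_km)


def _default_tariffs() -> dict[str, TariffParams]:
    # Placeholder approximations of French conventional medical-transport
    # tariffs (the exact schedules are jurisdiction- and year-specific);
    # fully configurable.
    return {
        "vsl": TariffParams(base_fare=13.70, per_km=0.93, minimum=13.70),
        "taxi": TariffParams(base_fare=2.30, per_km=1.35, minimum=7.30),
        "ambulance": TariffParams(base_fare=51.30, per_km=2.17, minimum=51.30),
    }


def _default_mode_probs() -> dict[str, float]:
    # Placeholder for the national shares of the three reimbursed transport
    # modes; configurable.
    return {"vsl": 0.45, "taxi": 0.40, "ambulance": 0.15}


@dataclass
class CostInputs:
    """Tariffs, prices, probabilities and counts of the cost model.

    Defaults are the study's 2020-euro inputs: €35.83 per specialist
    (tele)consultation, €12 nurse accompaniment fee, 26.56% of TCs via a
    telehealth station, 36% of patients medically transported, 12 stations
    (half full / half device-free "wallet"), 5-year straight-line
    depreciation, a 7-month observation window, 532 TC patients, and 30
    doctors using the videoconferencing software at €70/month each.
    """

    consult_fee: float = 35.83
    nurse_fee: float = 12.0
    p_tc_station: float = 0.2656
    share_med_transport: float = 0.36
    mode_probs: dict[str, float] = field(default_factory=_default_mode_probs)
    nonmed_rate: float = 0.523
    tariff_params: dict[str, TariffParams] = field(default_factory=_default_tariffs)
    station_full_price: float = 21_686.4
    station_wallet_price: float = 10_200.0
    installation: float = 1_680.0
    training_per_team: float = 1_020.0
    teams_per_station: int = 1
    maintenance_monthly: float = 90.0
    consumables_annual: float = 360.0
    med_equipment_per_station: float = 360.0
    # the device kit is charged only for stations that carry devices
    med_equipment_full_stations_only: bool = True
    n_stations: int = 12
    share_full_stations: float = 0.5
    amortization_months: int = 60
    n_months_window: float = 7.0
    n_tc_patients_total: int = 532
    n_doctors: int = 30
    software_monthly_per_user: float = 70.0
    headphone_per_user: float = 110.0

    def validate(self) -> None:
        for name in (
            "consult_fee",
            "nurse_fee",
            "nonmed_rate",
            "station_full_price",
            "station_wallet_price",
            "installation",
            "training_per_team",
            "maintenance_monthly",
            "consumables_annual",
            "med_equipment_per_station",
            "software_monthly_per_user",
            "headphone_per_user",
            "n_months_window",
        ):
            if getattr(self, name) < 0:
                raise CostModelError(f"{name} must be non-negative")
        for name in ("p_tc_station", "share_med_transport", "share_full_stations"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CostModelError(f"{name} must lie in [0, 1]")
        if abs(sum(self.mode_probs.values()) - 1.0) > 1e-9:
            raise CostModelError("mode_probs must sum to 1")
        if set(self.mode_probs) != set(self.tariff_params):
            raise CostModelError("mode_probs and tariff_params modes must match")
        if self.amortization_months <= 0:
            raise CostModelError("amortization_months must be positive")
        if self.n_tc_patients_total < 1:
            raise CostModelError("n_tc_patients_total must be at least 1")

    @property
    def n_full_stations(self) -> int:
        return int(round(self.n_stations * self.share_full_stations))

    @property
    def n_wallet_stations(self) -> int:
        return self.n_stations - self.n_full_stations


@dataclass(frozen=True)
class CostBreakdown:
    """Euro decomposition of one patient's total cost."""

    consult_cost: float
    nurse_fee_cost: float
    medical_transport: float
    nonmedical_transport: float
    equipment: float
    total: float

    @classmethod
    def build(cls, consult, nurse, med, nonmed, equip) -> "CostBreakdown":
        return cls(consult, nurse, med, nonmed, equip, consult + nurse + med + nonmed + equip)


def nonmedical_transport_cost(distance_km: float, inputs: CostInputs | None = None) -> float:
    """Official cost-per-kilometer valuation of personal-vehicle travel."""
    if distance_km < 0:
        raise CostModelError("distance_km must be non-negative")
    rate = inputs.nonmed_rate if inputs is not None else 0.523
    return rate * distance_km


def medical_transport_cost(distance_km: float, inputs: CostInputs) -> float:
    """Probability-weighted medical transport tariff for a given distance."""
    if distance_km < 0:
        raise CostModelError("distance_km must be non-negative")
    if abs(sum(inputs.mode_probs.values()) - 1.0) > 1e-9:
        raise CostModelError("mode_probs must sum to 1")
    return sum(
        p * inputs.tariff_params[mode](distance_km)
        for mode, p in inputs.mode_probs.items()
    )


def monthly_equipment_device(inputs: CostInputs) -> float:
    """Monthly cost of one full telehealth station.

    Purchase, installation and team training amortized straight-line;
    consumable medical equipment at its annual rate / 12.
    """
    depreciable = (
        inputs.station_full_price
        + inputs.installation
        + inputs.training_per_team * inputs.teams_per_station
    )
    return depreciable / inputs.amortization_months + inputs.consumables_annual / 12.0


def monthly_equipment_wallet(inputs: CostInputs) -> float:
    """Monthly cost of one device-free ("wallet") telehealth station."""
    depreciable = (
        inputs.station_wallet_price + inputs.training_per_team * inputs.teams_per_station
    )
    return depreciable / inputs.amortization_months + inputs.consumables_annual / 12.0


def equipment_cost_per_tc_patient(inputs: CostInputs) -> float:
    """Fixed teleconsultation infrastructure cost allocated to one TC patient.

    Monthly station costs (amortized purchase + consumables + maintenance)
    accrue over the observation window; one-off items (medical device kits,
    headset/camera per doctor) are charged once; software licences accrue
    monthly per doctor. The total is divided by the observed number of TC
    patients.
    """
    inputs.validate()
    n_full = inputs.n_full_stations
    n_wallet = inputs.n_wallet_stations
    monthly = (
        n_full * monthly_equipment_device(inputs)
        + n_wallet * monthly_equipment_wallet(inputs)
        + inputs.n_stations * inputs.maintenance_monthly
    )
    n_equipped = n_full if inputs.med_equipment_full_stations_only else inputs.n_stations
    total = (
        monthly * inputs.n_months_window
        + n_equipped * inputs.med_equipment_per_station
        + inputs.n_doctors * inputs.software_monthly_per_user * inputs.n_months_window
        + inputs.n_doctors * inputs.headphone_per_user
    )
    return total / inputs.n_tc_patients_total


def patient_total_cost(record, inputs: CostInputs) -> CostBreakdown:
    """Total cost of one patient's care pathway, decomposed.

    ``record`` needs attributes ``n_consult``, ``n_tc``, ``distance_km`` and
    ``group`` (``"TC"`` or ``"CS"``); both :class:`PatientRecord` and a
    population-frame row satisfy this.
    """
    n_consult = int(record.n_consult)
    n_tc = int(record.n_tc)
    n_physical = n_consult - n_tc
    if n_physical < 0:
        raise CostModelError("n_tc cannot exceed n_consult")
    consult = n_consult * inputs.consult_fee
    nurse = inputs.p_tc_station * n_tc * inputs.nurse_fee
    dist = 2.0 * float(record.distance_km) * n_physical
    if dist > 0:
        med = inputs.share_med_transport * medical_transport_cost(dist, inputs)
        nonmed = (1.0 - inputs.share_med_transport) * nonmedical_transport_cost(
            dist, inputs
        )
    else:
        med = nonmed = 0.0
    equip = equipment_cost_per_tc_patient(inputs) if record.group == "TC" else 0.0
    return CostBreakdown.build(consult, nurse, med, nonmed, equip)


def population_costs(population: pd.DataFrame, inputs: CostInputs) -> pd.DataFrame:
    """Vectorised per-patient cost table for a population frame.

    Returns one row per patient with the five components and the total,
    indexed like ``population``.
    """
    inputs.validate()
    n_consult = population["n_consult"].to_numpy(dtype=float)
    n_tc = population["n_tc"].to_numpy(dtype=float)
    n_physical = n_consult - n_tc
    if (n_physical < 0).any():
        raise CostModelError("n_tc cannot exceed n_consult")
    dist = 2.0 * population["distance_km"].to_numpy(dtype=float) * n_physical

    consult = n_consult * inputs.consult_fee
    nurse = inputs.p_tc_station * n_tc * inputs.nurse_fee

    med = np.zeros_like(dist)
    for mode, p in inputs.mode_probs.items():
        t = inputs.tariff_params[mode]
        med += p * np.maximum(t.minimum, t.base_fare + t.per_km * dist)
    med *= inputs.share_med_transport
    nonmed = (1.0 - inputs.share_med_transport) * inputs.nonmed_rate * dist
    travelled = dist > 0
    med = np.where(travelled, med, 0.0)
    nonmed = np.where(travelled, nonmed, 0.0)

    equip_unit = equipment_cost_per_tc_patient(inputs)
    equip = np.where(population["group"].to_numpy() == "TC", equip_unit, 0.0)

    out = pd.DataFrame(
        {
            "patient_id": population["patient_id"].to_numpy(),
            "group": population["group"].to_numpy(),
            "consult_cost": consult,
            "nurse_fee_cost": nurse,
            "medical_transport": med,
            "nonmedical_transport": nonmed,
            "equipment": equip,
        },
        index=population.index,
    )
    out["total"] = (
        out.consult_cost
        + out.nurse_fee_cost
        + out.medical_transport
        + out.nonmedical_transport
        + out.equipment
    )
    return out
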