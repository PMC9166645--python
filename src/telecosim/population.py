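"""Synthetic patient populations for teleconsultation cost studies.

Real teleconsultation (TC) cohorts are private clinical data, so every
analysis stage in this package runs against synthetic populations that
reproduce the statistical structure the method needs to see:

* categorical covariates (gender, ICD-10 chapter, care unit, consultation
  pathway type) drawn from the published marginal frequencies of a French
  private-hospital cohort (424 TC patients, 13,202 physical-consultation
  patients over a 298-day follow-up window);
* covariate-driven selection into the TC group, calibrated by default to the
  per-category log odds ratios implied by those published counts, so that
  propensity-score matching has genuine selection bias to remove;
* heavy-tailed road distances (lognormal) with a deterministic link to
  travel time via a fixed average speed;
* zero-truncated Poisson consultation counts with group-specific means
  (TC patients consult more often than control patients).

The population is materialised as a :class:`pandas.DataFrame`, one row per
patient, with per-consultation dates and TC flags serialised as
semicolon-joined strings so the table round-trips losslessly through
delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "PopulationParams",
    "PatientRecord",
    "ConfigurationError",
    "generate_population",
    "sample_agents",
    "write_population",
    "read_population",
    "TABLE_COUNTS",
    "POPULATION_COLUMNS",
]


class ConfigurationError(ValueError):
    """Raised when population parameters violate their invariants."""


# Published cohort counts (TC group n=424, control group n=13,202) used to
# derive default marginal frequencies and default selection coefficients.
TABLE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "gender": {
        "female": (216, 7119),
        "male": (208, 6083),
    },
    "pathway_type": {
        "after": (89, 3363),
        "before": (127, 5078),
        "both": (208, 4761),
    },
    "icd10_chapter": {
        "infectious": (0, 51),
        "neoplasms": (100, 1679),
        "blood": (0, 15),
        "endocrine": (15, 255),
        "mental": (0, 1),
        "nervous": (1, 236),
        "eye": (0, 774),
        "circulatory": (92, 1003),
        "respiratory": (0, 66),
        "digestive": (76, 2676),
        "skin": (1, 157),
        "musculoskeletal": (45, 2524),
        "genitourinary": (55, 1106),
        "pregnancy": (0, 1),
        "congenital": (2, 16),
        "symptoms": (10, 412),
        "injury": (1, 286),
        "factors": (26, 1944),
    },
    "care_unit": {
        "ambulatory_emergency": (0, 339),
        "ambulatory": (143, 3427),
        "short_stay": (55, 2397),
        "anesthesia": (1, 1),
        "other": (1, 0),
        "digestive_unit": (56, 1539),
        "sleep_assessment": (2, 974),
        "gastroenterology": (1, 110),
        "gynecology": (23, 566),
        "medicine": (4, 36),
        "neurology": (7, 117),
        "ophthalmology": (0, 22),
        "orthopedics": (19, 1741),
        "radiology": (0, 1),
        "resuscitation": (1, 193),
        "monitoring": (1, 384),
        "urology": (66, 712),
        "vascular": (44, 643),
    },
}

_COEF_CLIP = (-12.0, 4.0)

POPULATION_COLUMNS = [
    "patient_id",
    "age",
    "gender",
    "distance_km",
    "travel_time_min",
    "median_living_std",
    "pop_density",
    "icd10_chapter",
    "care_unit",
    "pathway_type",
    "consult_dates",
    "tc_flags",
    "group",
    "n_consult",
    "n_tc",
]

TC_GROUP = "TC"
CS_GROUP = "CS"


def _default_marginals() -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for cov, counts in TABLE_COUNTS.items():
        total = sum(tc + cs for tc, cs in counts.values())
        out[cov] = {cat: (tc + cs) / total for cat, (tc, cs) in counts.items()}
    return out


def _default_selection() -> dict[str, dict[str, float]]:
    """Per-category selection log odds ratios implied by the cohort counts.

    Categories never observed in the TC group get a strongly negative
    coefficient (they are effectively ineligible for teleconsultation),
    clipped so the logit stays finite.
    """
    out: dict[str, dict[str, float]] = {}
    for cov, counts in TABLE_COUNTS.items():
        n_tc = sum(tc for tc, _ in counts.values())
        n_cs = sum(cs for _, cs in counts.values())
        coefs = {}
        for cat, (tc, cs) in counts.items():
            if tc == 0:
                lo = _COEF_CLIP[0]
            elif cs == 0:
                lo = _COEF_CLIP[1]
            else:
                lo = float(np.log((tc / n_tc) / (cs / n_cs)))
            coefs[cat] = float(np.clip(lo, *_COEF_CLIP))
        out[cov] = coefs
    return out


@dataclass
class PopulationParams:
    """Generator configuration.

    Defaults reproduce the study conditions: a cohort of 13,626 patients of
    whom ~3.1% are TC patients, mean age ~61.5 years, mean one-way travel
    time ~24 minutes at 0.9 km/min, a 298-day follow-up window (165 days
    before + 133 days after the index hospital stay), and mean consultation
    counts of 3.53 (TC group) versus 2.94 (control group).
    """

    n_patients: int = 13_626
    tc_fraction_target: float = 424 / 13_626
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=_default_marginals
    )
    age_mean: float = 61.5
    age_sd: float = 16.0
    # lognormal one-way road distance; median exp(mu) ~ 15 km gives a mean
    # travel time of ~24 min at 0.9 km/min
    distance_log_mu: float = float(np.log(15.0))
    distance_log_sigma: float = 0.854
    travel_speed_km_per_min: float = 0.9
    living_std_mean: float = 19_873.0
    living_std_sd: float = 3_000.0
    pop_density_mean: float = 9.6
    pop_density_sd: float = 5.0
    selection_coefficients: dict[str, dict[str, float]] = field(
        default_factory=_default_selection
    )
    # linear logit coefficients on standardized continuous covariates
    continuous_selection: dict[str, float] = field(default_factory=dict)
    consult_mean_tc: float = 3.53
    consult_mean_cs: float = 2.94
    # per-consultation probability that a TC patient's visit is remote;
    # calibrated so mean TCs per TC patient ~ 1/0.8512
    tc_share_within_tc_patients: float = 1.0 / 0.8512 / 3.53
    followup_days: int = 165 + 133
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not 0.0 < self.tc_fraction_target < 1.0:
            raise ConfigurationError("tc_fraction_target must lie in (0, 1)")
        if self.followup_days <= 0:
            raise ConfigurationError("followup_days must be positive")
        if self.travel_speed_km_per_min <= 0:
            raise ConfigurationError("travel_speed_km_per_min must be positive")
        for cov, freqs in self.covariate_marginals.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"covariate_marginals[{cov!r}] sums to {tot}, expected 1"
                )
            if any(f < 0 for f in freqs.values()):
                raise ConfigurationError(
                    f"covariate_marginals[{cov!r}] has a negative frequency"
                )
        for cov in self.selection_coefficients:
            if cov not in self.covariate_marginals:
                raise ConfigurationError(
                    f"selection_coefficients references unknown covariate {cov!r}"
                )


@dataclass
class PatientRecord:
    """One patient: covariates, consultation history and group label."""

    patient_id: int
    age: float
    gender: str
    distance_km: float
    travel_time_min: float
    median_living_std: float
    pop_density: float
    icd10_chapter: str
    care_unit: str
    pathway_type: str
    consult_dates: tuple[int, ...]
    tc_flags: tuple[bool, ...]

    @property
    def n_consult(self) -> int:
        return len(self.consult_dates)

    @property
    def n_tc(self) -> int:
        return int(sum(self.tc_flags))

    @property
    def group(self) -> str:
        return TC_GROUP if any(self.tc_flags) else CS_GROUP


def _truncated_poisson_lambda(target_mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (> 1)."""
    if target_mean <= 1.0:
        raise ConfigurationError("zero-truncated Poisson mean must exceed 1")

    def gap(lam: float) -> float:
        return lam / (1.0 - np.exp(-lam)) - target_mean

    return float(optimize.brentq(gap, 1e-9, 10 * target_mean))


def _sample_zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson via inverse-cdf on the shifted uniform."""
    # P(N >= 1) = 1 - exp(-lam); draw U in (exp(-lam), 1) and invert
    u = rng.uniform(np.exp(-lam), 1.0, size=size)
    from scipy import stats

    return stats.poisson.ppf(u, lam).astype(int)


def _calibrate_intercept(linpred: np.ndarray, target: float) -> float:
    def gap(b0: float) -> float:
        return float(np.mean(special.expit(b0 + linpred)) - target)

    return float(optimize.brentq(gap, -30.0, 30.0))


def generate_population(params: PopulationParams) -> pd.DataFrame:
    """Draw a synthetic patient table; deterministic given ``params.seed``.

    Categorical covariates are sampled independently from the configured
    marginals; a logit over those covariates (plus optional standardized
    continuous terms) then selects patients into the TC group, with the
    intercept solved numerically so the expected TC fraction matches
    ``tc_fraction_target``. Consultation counts are zero-truncated Poisson
    per group; consultation dates are uniform over the follow-up window;
    each TC-group consultation is remote with a fixed per-visit probability,
    with at least one remote visit forced per TC patient.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    cats: dict[str, np.ndarray] = {}
    for cov, freqs in params.covariate_marginals.items():
        names = list(freqs)
        p = np.array([freqs[c] for c in names], dtype=float)
        p /= p.sum()
        cats[cov] = rng.choice(names, size=n, p=p)

    age = rng.normal(params.age_mean, params.age_sd, size=n).clip(18.0, 100.0)
    distance = rng.lognormal(params.distance_log_mu, params.distance_log_sigma, size=n)
    travel_time = distance / params.travel_speed_km_per_min
    living = rng.normal(params.living_std_mean, params.living_std_sd, size=n).clip(
        min=8_000.0
    )
    density = rng.gamma(
        (params.pop_density_mean / params.pop_density_sd) ** 2,
        params.pop_density_sd**2 / params.pop_density_mean,
        size=n,
    )

    linpred = np.zeros(n)
    for cov, coefs in params.selection_coefficients.items():
        vals = cats[cov]
        lut = {c: coefs.get(c, 0.0) for c in set(vals)}
        linpred += np.array([lut[v] for v in vals])
    continuous = {
        "age": age,
        "distance_km": distance,
        "travel_time_min": travel_time,
        "median_living_std": living,
        "pop_density": density,
    }
    for name, beta in params.continuous_selection.items():
        if name not in continuous:
            raise ConfigurationError(
                f"continuous_selection references unknown covariate {name!r}"
            )
        x = continuous[name]
        linpred += beta * (x - x.mean()) / (x.std() or 1.0)

    b0 = _calibrate_intercept(linpred, params.tc_fraction_target)
    p_tc = special.expit(b0 + linpred)
    is_tc = rng.uniform(size=n) < p_tc

    lam_tc = _truncated_poisson_lambda(params.consult_mean_tc)
    lam_cs = _truncated_poisson_lambda(params.consult_mean_cs)
    n_consult = np.where(
        is_tc,
        _sample_zt_poisson(rng, lam_tc, n),
        _sample_zt_poisson(rng, lam_cs, n),
    )

    q = params.tc_share_within_tc_patients
    consult_dates: list[str] = []
    tc_flags: list[str] = []
    n_tc_arr = np.zeros(n, dtype=int)
    for i in range(n):
        k = int(n_consult[i])
        dates = np.sort(rng.integers(0, params.followup_days + 1, size=k))
        if is_tc[i]:
            flags = rng.uniform(size=k) < q
            if not flags.any():
                flags[rng.integers(0, k)] = True
        else:
            flags = np.zeros(k, dtype=bool)
        n_tc_arr[i] = int(flags.sum())
        consult_dates.append(";".join(str(int(d)) for d in dates))
        tc_flags.append(";".join("1" if f else "0" for f in flags))

    return pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=int),
            "age": age,
            "gender": cats["gender"],
            "distance_km": distance,
            "travel_time_min": travel_time,
            "median_living_std": living,
            "pop_density": density,
            "icd10_chapter": cats["icd10_chapter"],
            "care_unit": cats["care_unit"],
            "pathway_type": cats["pathway_type"],
            "consult_dates": consult_dates,
            "tc_flags": tc_flags,
            "group": np.where(is_tc, TC_GROUP, CS_GROUP),
            "n_consult": n_consult,
            "n_tc": n_tc_arr,
        }
    )


def sample_agents(
    population: pd.DataFrame,
    n_days: int,
    arrival_rate: float,
    seed: int,
    population_filter=None,
) -> pd.DataFrame:
    """Day-indexed agent stream: Poisson daily arrivals, attributes resampled
    from ``population`` rows with replacement.

    ``population_filter`` is an optional boolean predicate over the population
    frame (e.g. ``lambda df: df.age > 80``) applied before resampling.
    """
    if n_days <= 0:
        raise ConfigurationError("n_days must be positive")
    if arrival_rate <= 0:
        raise ConfigurationError("arrival_rate must be positive")
    pool = population
    if population_filter is not None:
        pool = population[np.asarray(population_filter(population), dtype=bool)]
    if pool.empty:
        raise ConfigurationError("population filter leaves no eligible patients")

    rng = np.random.default_rng(seed)
    counts = rng.poisson(arrival_rate, size=n_days)
    idx = rng.integers(0, len(pool), size=int(counts.sum()))
    agents = pool.iloc[idx].reset_index(drop=True)
    agents.insert(0, "day", np.repeat(np.arange(n_days), counts))
    return agents


def write_population(population: pd.DataFrame, path) -> None:
    """Write the population table as UTF-8 CSV with '.' decimal separator."""
    population.to_csv(path, index=False, columns=POPULATION_COLUMNS)


def read_population(path) -> pd.DataFrame:
    """Read a population table, validating per-row consistency.

    Raises :class:`ConfigurationError` listing the offending line numbers if
    any row has malformed consultation history or an inconsistent group
    label (header is line 1; data rows start at line 2).
    """
    df = pd.read_csv(path, dtype={"consult_dates": str, "tc_flags": str})
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"population file lacks columns: {missing}")
    bad: list[int] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            dates = _parse_int_list(row["consult_dates"])
            flags = _parse_int_list(row["tc_flags"])
            if len(dates) != len(flags) or len(dates) == 0:
                raise ValueError
            if any(f not in (0, 1) for f in flags):
                raise ValueError
            expected_group = TC_GROUP if any(flags) else CS_GROUP
            if row["group"] != expected_group:
                raise ValueError
            if int(row["n_consult"]) != len(dates) or int(row["n_tc"]) != sum(flags):
                raise ValueError
        except (ValueError, TypeError):
            bad.append(line)
    if bad:
        raise ConfigurationError(f"malformed population rows at lines: {bad}")
    return df


def _parse_int_list(cell) -> list[int]:
    if not isinstance(cell, str) or cell == "":
        raise ValueError("empty consultation list")
    return [int(tok) for tok in cell.split(";")]


def records_from_frame(population: pd.DataFrame) -> list[PatientRecord]:
    """Materialise :class:`PatientRecord` objects from a population frame."""
    out = []
    for row in population.itertuples(index=False):
        out.append(
            PatientRecord(
                patient_id=int(row.patient_id),
                age=float(row.age),
                gender=str(row.gender),
                distance_km=float(row.distance_km),
                travel_time_min=float(row.travel_time_min),
                median_living_std=float(row.median_living_std),
                pop_density=float(row.pop_density),
                icd10_chapter=str(row.icd10_chapter),
                care_unit=str(row.care_unit),
                pathway_type=str(row.pathway_type),
                consult_dates=tuple(int(t) for t in str(row.consult_dates).split(";")),
                tc_flags=tuple(t == "1" for t in str(row.tc_flags).split(";")),
            )
        )
    return out
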