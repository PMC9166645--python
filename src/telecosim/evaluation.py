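"""Matched incremental-cost analysis.

Selection into teleconsultation is not random: eligibility depends on
diagnosis, care unit and care-pathway shape, so a naive group comparison of
costs is confounded. The pipeline here is the standard observational
remedy:

1. fit a logit propensity model — the conditional probability of belonging
   to the TC group given the covariates suspected of driving selection;
2. 1:1 greedy nearest-neighbour matching on the propensity score, without
   replacement, TC patients processed in descending score order;
3. balance diagnostics before/after matching (group means, two-sample
   tests, standardized mean differences);
4. incremental cost = difference of matched group mean total costs, with a
   non-parametric bootstrap percentile CI (resampling patients with
   replacement within each matched group);
5. a tornado-style deterministic sensitivity analysis that re-evaluates the
   incremental cost under one-at-a-time changes to the cost inputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .costs import CostInputs, population_costs

__all__ = [
    "PropensityModel",
    "MatchedSample",
    "IncrementalCostResult",
    "TornadoScenario",
    "EvaluationError",
    "DEFAULT_COVARIATES",
    "fit_propensity",
    "match_1to1",
    "balance_table",
    "incremental_cost",
    "bootstrap_incremental",
    "tornado",
    "evaluate_incremental_cost",
]


class EvaluationError(ValueError):
    pass


DEFAULT_COVARIATES = [
    "age",
    "gender",
    "travel_time_min",
    "median_living_std",
    "pop_density",
    "pathway_type",
    "icd10_chapter",
    "care_unit",
]

_CONTINUOUS = {"age", "travel_time_min", "median_living_std", "pop_density", "distance_km"}


@dataclass
class PropensityModel:
    coefficients: pd.Series
    scores: pd.Series  # indexed by patient_id, strictly in (0, 1)
    converged: bool
    log_likelihood: float
    covariates: list[str]


@dataclass
class MatchedSample:
    pairs: list[tuple[int, int]]  # (TC patient_id, CS patient_id)
    unmatched: list[int]
    balance: pd.DataFrame | None = None

    @property
    def tc_ids(self) -> list[int]:
        return [a for a, _ in self.pairs]

    @property
    def cs_ids(self) -> list[int]:
        return [b for _, b in self.pairs]

    @property
    def matched_ids(self) -> list[int]:
        return self.tc_ids + self.cs_ids


@dataclass
class IncrementalCostResult:
    mean_total_tc: float
    mean_total_cs: float
    incremental: float
    bootstrap_ci: tuple[float, float] | None
    n_bootstrap: int
    seed: int | None


@dataclass
class TornadoScenario:
    label: str
    modifications: dict
    incremental: float
    deviation: float  # signed difference from the base incremental cost


def _design_matrix(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cont = [c for c in covariates if c in _CONTINUOUS]
    cat = [c for c in covariates if c not in _CONTINUOUS]
    parts = []
    if cont:
        # z-score continuous covariates: the fitted scores are invariant to
        # affine rescaling, and unscaled columns (e.g. euros ~2e4) break the
        # optimizer's line search
        Xc = df[cont].astype(float)
        parts.append((Xc - Xc.mean()) / Xc.std().replace(0.0, 1.0))
    if cat:
        dummies = pd.get_dummies(df[cat].astype(str), drop_first=True, dtype=float)
        parts.append(dummies)
    X = pd.concat(parts, axis=1)
    # drop constant columns (categories absent from this sample)
    X = X.loc[:, X.std() > 0]
    return sm.add_constant(X, has_constant="add")


def fit_propensity(
    population: pd.DataFrame, covariates: list[str] | None = None
) -> PropensityModel:
    """Maximum-likelihood logit of TC-group membership on the covariates.

    Continuous covariates enter linearly; categorical covariates as full
    indicator sets with one reference level each. Raises
    :class:`EvaluationError` on perfect separation instead of silently
    dropping covariates.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    y = (population["group"] == "TC").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise EvaluationError("both groups must be non-empty to fit a propensity model")
    X = _design_matrix(population, covariates)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(method="lbfgs", maxiter=1000, disp=0)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise EvaluationError(
            f"propensity logit failed ({exc}); review the covariate list for "
            "perfectly separating variables"
        ) from exc
    if not np.isfinite(fit.llf) or np.allclose(np.asarray(fit.params), 0.0):
        raise EvaluationError(
            "propensity logit did not move from its starting values; review "
            "covariate scaling and separation"
        )
    scores = np.asarray(fit.predict(X), dtype=float)
    if (scores > 0.5).astype(float).tolist() == y.tolist() and len(np.unique(y)) == 2:
        # complete prediction => the MLE does not exist
        raise EvaluationError(
            "perfect separation detected: the covariates classify the groups "
            "exactly; review the covariate list"
        )
    eps = 1e-12
    scores = np.clip(scores, eps, 1 - eps)
    return PropensityModel(
        coefficients=pd.Series(fit.params, index=X.columns),
        scores=pd.Series(scores, index=population["patient_id"].to_numpy()),
        converged=bool(fit.mle_retvals.get("converged", True)),
        log_likelihood=float(fit.llf),
        covariates=covariates,
    )


def match_1to1(scores: pd.Series, groups: pd.Series) -> MatchedSample:
    """Greedy 1:1 nearest-neighbour matching on the propensity score.

    TC patients are processed in descending score order (ties by smallest
    patient id) and matched without replacement to the closest remaining CS
    patient (distance ties by smallest patient id).
    """
    ids = np.asarray(scores.index)
    sc = scores.to_numpy(dtype=float)
    grp = np.asarray(groups)
    tc_mask = grp == "TC"
    cs_mask = grp == "CS"
    n_tc, n_cs = int(tc_mask.sum()), int(cs_mask.sum())
    if n_cs < n_tc:
        raise EvaluationError(
            f"cannot 1:1 match {n_tc} TC patients against only {n_cs} CS patients"
        )

    tc_order = np.lexsort((ids[tc_mask], -sc[tc_mask]))
    tc_ids = ids[tc_mask][tc_order]
    tc_sc = sc[tc_mask][tc_order]

    cs_ids = ids[cs_mask]
    cs_sc = sc[cs_mask]
    alive = np.ones(n_cs, dtype=bool)

    pairs: list[tuple[int, int]] = []
    for t_id, t_sc in zip(tc_ids, tc_sc):
        d = np.abs(cs_sc - t_sc)
        d_alive = d[alive]
        dmin = d_alive.min()
        cand = alive & (d == dmin)
        j = np.flatnonzero(cand)[np.argmin(cs_ids[np.flatnonzero(cand)])]
        pairs.append((int(t_id), int(cs_ids[j])))
        alive[j] = False
    unmatched = [int(i) for i in cs_ids[alive]]
    return MatchedSample(pairs=pairs, unmatched=unmatched)


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    pooled = np.sqrt((np.var(x_t, ddof=1) + np.var(x_c, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((x_t.mean() - x_c.mean()) / pooled)


def balance_table(
    population: pd.DataFrame, covariates: list[str], matched: MatchedSample | None = None
) -> pd.DataFrame:
    """Per-covariate group means, test p-values and standardized mean
    differences; continuous covariates use a two-sample t-test, category
    levels a two-proportion z-test.

    If ``matched`` is given, the table is computed on the matched subsample.
    """
    df = population
    if matched is not None:
        df = population[population["patient_id"].isin(matched.matched_ids)]
    tc = df[df["group"] == "TC"]
    cs = df[df["group"] == "CS"]
    rows = []
    for cov in covariates:
        if cov in _CONTINUOUS:
            x_t = tc[cov].to_numpy(dtype=float)
            x_c = cs[cov].to_numpy(dtype=float)
            _, p = stats.ttest_ind(x_t, x_c, equal_var=False)
            rows.append(
                {
                    "covariate": cov,
                    "level": "",
                    "mean_tc": x_t.mean(),
                    "mean_cs": x_c.mean(),
                    "p_value": float(p),
                    "smd": _smd(x_t, x_c),
                }
            )
        else:
            for level in sorted(df[cov].astype(str).unique()):
                x_t = (tc[cov].astype(str) == level).to_numpy(dtype=float)
                x_c = (cs[cov].astype(str) == level).to_numpy(dtype=float)
                p = _prop_test(x_t, x_c)
                rows.append(
                    {
                        "covariate": cov,
                        "level": level,
                        "mean_tc": x_t.mean(),
                        "mean_cs": x_c.mean(),
                        "p_value": p,
                        "smd": _smd(x_t, x_c),
                    }
                )
    return pd.DataFrame(rows)


def _prop_test(x_t: np.ndarray, x_c: np.ndarray) -> float:
    n1, n2 = len(x_t), len(x_c)
    p1, p2 = x_t.mean(), x_c.mean()
    p_pool = (x_t.sum() + x_c.sum()) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2 * stats.norm.sf(abs(z)))


def incremental_cost(
    matched: MatchedSample, costs: pd.DataFrame
) -> IncrementalCostResult:
    """Point estimate: difference of matched group mean total costs.

    ``costs`` is a per-patient cost table with ``patient_id``, ``group`` and
    ``total`` columns (see :func:`telecosim.costs.population_costs`).
    """
    if not matched.pairs:
        raise EvaluationError("matched sample is empty")
    by_id = costs.set_index("patient_id")["total"]
    tc_costs = by_id.loc[matched.tc_ids].to_numpy(dtype=float)
    cs_costs = by_id.loc[matched.cs_ids].to_numpy(dtype=float)
    return IncrementalCostResult(
        mean_total_tc=float(tc_costs.mean()),
        mean_total_cs=float(cs_costs.mean()),
        incremental=float(tc_costs.mean() - cs_costs.mean()),
        bootstrap_ci=None,
        n_bootstrap=0,
        seed=None,
    )


def bootstrap_incremental(
    tc_costs: np.ndarray,
    cs_costs: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the incremental cost.

    Patients are resampled with replacement within each group (unpaired);
    deterministic given ``seed``.
    """
    if n_bootstrap < 1:
        raise EvaluationError("n_bootstrap must be at least 1")
    tc = np.asarray(tc_costs, dtype=float)
    cs = np.asarray(cs_costs, dtype=float)
    rng = np.random.default_rng(seed)
    idx_t = rng.integers(0, len(tc), size=(n_bootstrap, len(tc)))
    idx_c = rng.integers(0, len(cs), size=(n_bootstrap, len(cs)))
    reps = tc[idx_t].mean(axis=1) - cs[idx_c].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    low, high = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(low), float(high)


_COST_FIELDS = {f.name for f in dataclasses.fields(CostInputs)}


def tornado(
    matched_population: pd.DataFrame,
    base_inputs: CostInputs,
    scenarios: list[tuple[str, dict]],
) -> list[TornadoScenario]:
    """One-at-a-time deterministic sensitivity of the incremental cost.

    Each scenario names :class:`CostInputs` fields to override; the matched
    incremental cost is recomputed with only those fields changed. The base
    (empty-modification) scenario is always evaluated and results are
    sorted by absolute deviation from it, descending, base last.
    """
    if not scenarios:
        raise EvaluationError("scenario list is empty")
    for label, mods in scenarios:
        unknown = set(mods) - _COST_FIELDS
        if unknown:
            raise EvaluationError(
                f"scenario {label!r} modifies unknown cost inputs {sorted(unknown)}; "
                f"valid names: {sorted(_COST_FIELDS)}"
            )

    def _incremental(inputs: CostInputs) -> float:
        costs = population_costs(matched_population, inputs)
        tc = costs.loc[costs["group"] == "TC", "total"]
        cs = costs.loc[costs["group"] == "CS", "total"]
        return float(tc.mean() - cs.mean())

    base = _incremental(base_inputs)
    out = [TornadoScenario("base", {}, base, 0.0)]
    for label, mods in scenarios:
        inc = _incremental(replace(base_inputs, **mods))
        out.append(TornadoScenario(label, dict(mods), inc, inc - base))
    out.sort(key=lambda s: abs(s.deviation), reverse=True)
    return out


def evaluate_incremental_cost(
    population: pd.DataFrame,
    inputs: CostInputs,
    covariates: list[str] | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[PropensityModel, MatchedSample, IncrementalCostResult]:
    """Full pipeline: propensity fit, matching, costs, incremental + CI."""
    model = fit_propensity(population, covariates)
    groups = pd.Series(
        population["group"].to_numpy(), index=population["patient_id"].to_numpy()
    )
    matched = match_1to1(model.scores, groups)
    costs = population_costs(population, inputs)
    point = incremental_cost(matched, costs)
    by_id = costs.set_index("patient_id")["total"]
    ci = bootstrap_incremental(
        by_id.loc[matched.tc_ids].to_numpy(),
        by_id.loc[matched.cs_ids].to_numpy(),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
    point.bootstrap_ci = ci
    point.n_bootstrap = n_bootstrap
    point.seed = seed
    return model, matched, point
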