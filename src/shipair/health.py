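"""Concentration-response health burden: premature cardiovascular and
lung-cancer mortality (30+ cohort) and childhood asthma morbidity (under-14
cohort) from gridded PM2.5 scenario pairs.

Per cell, the excess annual cases are E = AF * B * P with attributable
fraction AF = (RR - 1)/RR. The "linear" concentration-response form is
RR = exp(beta * (C1 - C0)) (so AF = 1 - exp(beta * (C0 - C1)) identically);
the log-linear alternative is RR = ((C1 + 1)/(C0 + 1))**beta (Ostro 2004
convention). Beta coefficients default to the Lepeule et al. (2012) updates of
the Harvard Six Cities study for mortality and Zheng et al. (2015) for
childhood asthma, with their 95% confidence intervals propagated to burden
bounds by re-evaluating E at the interval ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import SEA, CountryMap, IncidenceTable, PopulationGrid


class InputError(ValueError):
    pass


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class CRModel:
    """A concentration-response specification for one endpoint."""

    endpoint: str               # CV | LC | ASTHMA
    form: str                   # linear | log_linear
    beta: float                 # per ug/m3
    ci_low: float
    ci_high: float
    cohort: str                 # age30plus | under14

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise InputError("beta must lie within its confidence interval")
        if self.form not in ("linear", "log_linear"):
            raise InputError(f"unknown C-R form {self.form!r}")

    def with_beta(self, beta: float) -> "CRModel":
        return CRModel(self.endpoint, self.form, beta,
                       min(beta, self.ci_low), max(beta, self.ci_high), self.cohort)


#: Lepeule et al. (2012) linear-form coefficients; Zheng et al. (2015) asthma.
LEPEULE_CV = CRModel("CV", "linear", 0.023111, 0.013103, 0.033647, "age30plus")
LEPEULE_LC = CRModel("LC", "linear", 0.031481, 0.006766, 0.055962, "age30plus")
ZHENG_ASTHMA = CRModel("ASTHMA", "linear", 0.002469, 0.001291, 0.003633, "under14")

#: Ostro (2004) lung-cancer coefficients: the "linear formulation" slope and
#: the log-linear-form exponent, used for cross-study comparison.
OSTRO_LC_BETA_LINEAR = 0.01267
OSTRO_LC_BETA_LOGLINEAR = 0.23218

DEFAULT_MODELS = {"CV": LEPEULE_CV, "LC": LEPEULE_LC, "ASTHMA": ZHENG_ASTHMA}

ENDPOINT_INCIDENCE = {"CV": "B_cv", "LC": "B_lc", "ASTHMA": "B_asthma"}


def relative_risk(model: CRModel, c0, c1):
    """RR for a concentration change C0 -> C1 (both >= 0); RR = 1 at C1 = C0."""
    c0 = np.asarray(c0, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    if np.any(c0 < 0) or np.any(c1 < 0):
        raise InputError("concentrations must be non-negative")
    if model.form == "linear":
        return np.exp(model.beta * (c1 - c0))
    return ((c1 + 1.0) / (c0 + 1.0)) ** model.beta


def attributable_fraction(rr):
    """AF = (RR - 1) / RR."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise InputError("relative risk must be positive")
    return (rr - 1.0) / rr


def af_linear(beta: float, c0, c1):
    """Direct linear-form AF = 1 - exp(beta * (C0 - C1)); equals
    (RR-1)/RR with RR = exp(beta*(C1-C0)) to machine precision."""
    c0 = np.asarray(c0, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    if np.any(c0 < 0) or np.any(c1 < 0):
        raise InputError("concentrations must be non-negative")
    return -np.expm1(beta * (c0 - c1))


def excess_cases(af, b_per_100k, population):
    """E = AF * B * P, annual cases; B given per 100,000 cohort persons/year."""
    af = np.asarray(af, dtype=float)
    b = np.asarray(b_per_100k, dtype=float)
    p = np.asarray(population, dtype=float)
    if np.any(b < 0) or np.any(p < 0):
        raise InputError("incidence rate and population must be non-negative")
    return af * (b / 1e5) * p


def cohort_population(population: PopulationGrid, country_map: CountryMap,
                      cohort: str) -> np.ndarray:
    """Per-cell persons in an age cohort: cell persons x the country's cohort
    fraction (uniform within each country). Countries without a stated
    fraction fall back to the mean over countries that have one."""
    fractions = {"age30plus": country_map.cohort_fraction_30plus,
                 "under14": country_map.cohort_fraction_under14}.get(cohort)
    if fractions is None:
        raise InputError(f"unknown cohort {cohort!r}")
    fallback = float(np.mean(list(fractions.values()))) if fractions else 0.0
    frac_grid = np.zeros(country_map.country_id.shape)
    for c in np.unique(country_map.country_id):
        if c == SEA:
            continue
        frac_grid[country_map.country_id == c] = fractions.get(int(c), fallback)
    return population.persons * frac_grid


def asr_to_crude(asr: float, nonasr_to_asr_ratio: float) -> float:
    """Crude incidence rate from an age-standardised rate and the
    population-structure crude:ASR ratio."""
    if asr <= 0 or nonasr_to_asr_ratio <= 0:
        raise InputError("ASR and ratio must be positive")
    return asr * nonasr_to_asr_ratio


@dataclass
class BurdenResult:
    """Gridded and per-country excess cases for one scenario pair.

    ``cells``: endpoint -> (n_lat, n_lon) central estimates;
    ``by_country``: rows (country, endpoint, E_low, E_central, E_high).
    """

    scenario_pair: str
    cells: dict[str, np.ndarray]
    by_country: pd.DataFrame

    def total(self, endpoint: str, column: str = "E_central") -> float:
        sub = self.by_country[self.by_country.endpoint == endpoint]
        return float(sub[column].sum())

    def combined_mortality(self, column: str = "E_central") -> float:
        return self.total("CV", column) + self.total("LC", column)


def compute_burden(
    c0: np.ndarray, c1: np.ndarray,
    population: PopulationGrid, country_map: CountryMap,
    incidence: IncidenceTable,
    models: dict[str, CRModel] | None = None,
    scenario_pair: str = "",
) -> BurdenResult:
    """Per-cell and per-country burden for concentration pair (C0, C1).

    C0 is the counterfactual (e.g. no-shipping), C1 the scenario field. All CV
    and LC deaths are attributed to the 30+ cohort, asthma to under-14, with
    country incidence rates applied uniformly over the country's cells.
    """
    models = DEFAULT_MODELS if models is None else models
    cohorts = {"age30plus": cohort_population(population, country_map, "age30plus"),
               "under14": cohort_population(population, country_map, "under14")}
    country_id = country_map.country_id
    rate_grids: dict[str, np.ndarray] = {}
    for endpoint, model in models.items():
        col = ENDPOINT_INCIDENCE[endpoint]
        rg = np.zeros(country_id.shape)
        for c in np.unique(country_id):
            if c == SEA:
                continue
            rg[country_id == c] = incidence.rate(int(c), col)
        rate_grids[endpoint] = rg

    cells: dict[str, np.ndarray] = {}
    rows = []
    for endpoint, model in models.items():
        pop = cohorts[model.cohort]
        b = rate_grids[endpoint]
        per_beta = {}
        for tag, beta in (("E_low", model.ci_low), ("E_central", model.beta),
                          ("E_high", model.ci_high)):
            af = attributable_fraction(relative_risk(model.with_beta(beta), c0, c1))
            per_beta[tag] = excess_cases(af, b, pop)
        cells[endpoint] = per_beta["E_central"]
        for c in np.unique(country_id):
            if c == SEA:
                continue
            m = country_id == c
            rows.append({"country": int(c), "endpoint": endpoint,
                         **{tag: float(arr[m].sum()) for tag, arr in per_beta.items()}})
    by_country = pd.DataFrame(rows, columns=["country", "endpoint",
                                             "E_low", "E_central", "E_high"])
    return BurdenResult(scenario_pair=scenario_pair, cells=cells,
                        by_country=by_country)


def aggregate(burden: BurdenResult, region_scheme: dict[int, str]) -> pd.DataFrame:
    """Country table -> region and global totals with percent shares.

    Every country must map to exactly one region; sums are preserved exactly
    (global = sum of regions = sum of countries).
    """
    tab = burden.by_country.copy()
    unmapped = set(tab.country.unique()) - set(region_scheme)
    if unmapped:
        raise AggregationError(f"countries without a region: {sorted(unmapped)}")
    tab["region"] = tab.country.map(region_scheme)
    by_region = tab.groupby(["region", "endpoint"], as_index=False)[
        ["E_low", "E_central", "E_high"]].sum()
    totals = by_region.groupby("endpoint")["E_central"].transform("sum")
    by_region["share_pct"] = np.where(totals > 0,
                                      100.0 * by_region.E_central / totals, 0.0)
    glob = by_region.groupby("endpoint", as_index=False)[
        ["E_low", "E_central", "E_high"]].sum()
    glob.insert(0, "region", "GLOBAL")
    glob["share_pct"] = np.where(glob.E_central.abs() > 0, 100.0, 0.0)
    return pd.concat([by_region, glob], ignore_index=True)


def percent_reduction(burden_a: float, burden_b: float) -> float:
    """100 * (a - b) / a; the relative reduction from a to b."""
    if burden_a == 0:
        raise InputError("zero baseline burden; percent reduction undefined")
    return 100.0 * (burden_a - burden_b) / burden_a


def round_for_report(value: float, endpoint: str) -> float:
    """Report rounding: mortality to the nearest 100 cases, childhood asthma
    to the nearest 100,000."""
    step = 100_000 if endpoint == "ASTHMA" else 100
    return float(step * round(value / step))
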