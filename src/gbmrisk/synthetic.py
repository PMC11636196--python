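"""Synthetic, statistically faithful inputs with known analytic truths.

Two generators make every pipeline stage testable without external
data: :func:`make_scenario` builds a complete material-flow scenario
(row-stochastic share matrices from Dirichlet rows, lognormal yearly
production, a small compartment graph whose expected sink masses have a
closed form) and :func:`make_hazard_dataset` builds a toxicity-record
table whose species sensitivities follow a lognormal law with a known
analytic 5% quantile (the true HC5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dpmfa import (Compartment, CompartmentGraph, ReleaseSchedule, Scenario,
                    TransferCoefficientPrior)
from .errors import GbmRiskError
from .hazard import ToxicityRecord
from .shares import (DEFAULT_FORM_SPLITS, GBM_FORMS, ProductionSeries,
                     ShareMatrix)


@dataclass(frozen=True)
class SyntheticScenarioSpec:
    """Controls for the synthetic material-flow scenario.

    Production follows a lognormal law with the given median (tonnes per
    year) and coefficient of variation; a zero CV gives deterministic
    production.  ``tc_spread`` widens each transfer-coefficient prior
    into a triangular prior of that half-width around the toy graph's
    nominal split (0 keeps point priors).  ``use_release_fraction`` is
    the geometric yearly release fraction of the in-use stock (1 =
    immediate release).
    """

    n_categories: int = 14
    n_forms: int = 3
    horizon_years: int = 10
    start_year: int = 2021
    production_median_t: float = 1000.0
    production_cv: float = 0.5
    tc_spread: float = 0.0
    use_release_fraction: float = 1.0
    n_runs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if min(self.n_categories, self.n_forms, self.horizon_years, self.n_runs) < 1:
            raise GbmRiskError("counts must be >= 1")
        if self.production_cv < 0:
            raise GbmRiskError("coefficient of variation must be >= 0")
        if not 0 < self.use_release_fraction <= 1:
            raise GbmRiskError("release fraction must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticHazardSpec:
    """Controls for the synthetic toxicity dataset.

    Species sensitivities are lognormal: log-median ``mu`` and log-sd
    ``sigma`` in ln(mg/L).  The default spread (sigma = 0.5) keeps the
    intrinsic small-sample bias of an empirical 5th percentile over
    ``n_species`` species well below sampling noise; real datasets can
    span several orders of magnitude and are emulated by raising sigma.
    Endpoints scatter lognormally (``sigma_within``) around each
    species' sensitivity, and ``descriptor_mix`` fixes the fractions of
    chronic NOEC / acute ECx / acute LCx records (acute records are
    stored pre-multiplied by the uncertainty factors so the conversion
    recovers the intended chronic NOEC exactly).
    """

    n_species: int = 26
    endpoints_total: int = 113
    mu: float = 0.0
    sigma: float = 0.5
    sigma_within: float = 0.3
    descriptor_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)
    form: str = "GBM"
    groups: tuple[str, ...] = ("fish", "algae", "daphnid", "amphibian",
                               "plant", "other")
    species_prefix: str = "species"
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise GbmRiskError("n_species must be >= 1")
        if self.sigma < 0 or self.sigma_within < 0:
            raise GbmRiskError("sigma values must be >= 0")
        if self.endpoints_total < self.n_species:
            raise GbmRiskError("need at least one endpoint per species")
        if abs(sum(self.descriptor_mix) - 1.0) > 1e-9:
            raise GbmRiskError("descriptor mix fractions must sum to 1")


@dataclass
class ScenarioBundle:
    """make_scenario output: scenario plus matrices and analytic truths."""

    scenario: Scenario
    E: ShareMatrix
    F: ShareMatrix
    production: ProductionSeries
    expected_sinks: dict[str, float]
    spec: SyntheticScenarioSpec


#: Nominal transfer coefficients of the shipped toy compartment graph.
TOY_SPLITS = {
    "production": {"use": 1.0},
    "use": {"wwtp": 0.4, "landfill": 0.3, "air": 0.2, "elimination": 0.1},
    "air": {"natural_soil": 1.0},
    "wwtp": {"surface_water": 0.05, "sludge_soil": 0.95},
}

TOY_COMPARTMENTS = [
    Compartment("production", "technical"),
    Compartment("use", "technical"),
    Compartment("air", "transfer"),
    Compartment("wwtp", "technical"),
    Compartment("surface_water", "environmental"),
    Compartment("natural_soil", "environmental"),
    Compartment("sludge_soil", "environmental"),
    Compartment("landfill", "sink"),
    Compartment("elimination", "elimination"),
]


def toy_graph() -> CompartmentGraph:
    edges = [(s, t) for s, tgts in TOY_SPLITS.items() for t in tgts]
    return CompartmentGraph(TOY_COMPARTMENTS, edges)


def make_scenario(spec: SyntheticScenarioSpec) -> ScenarioBundle:
    """Complete synthetic scenario with closed-form expected sink masses.

    Share matrices use Dirichlet(1, ..., 1) rows (uniform on the
    simplex, always row-stochastic).  The expected mass reaching each
    terminal compartment over the horizon follows from linearity: the
    expected total production times the nominal path coefficients (the
    triangular TC priors are symmetric around the nominal splits, and
    renormalisation of an already-normalised vector is exact for point
    priors).
    """
    rng = np.random.default_rng(spec.seed)
    years = tuple(range(spec.start_year, spec.start_year + spec.horizon_years))
    # reuse the shipped product-category vocabulary when the count matches,
    # so synthetic E matrices compose with the default form-split matrix
    if spec.n_categories == len(DEFAULT_FORM_SPLITS):
        cats = tuple(DEFAULT_FORM_SPLITS)
    else:
        cats = tuple(f"category_{i + 1}" for i in range(spec.n_categories))
    forms = tuple(GBM_FORMS[: spec.n_forms]) if spec.n_forms <= 3 else tuple(
        f"form_{i + 1}" for i in range(spec.n_forms))

    E = ShareMatrix(years, cats, rng.dirichlet(np.ones(spec.n_categories),
                                               size=len(years)))
    F = ShareMatrix(cats, forms, rng.dirichlet(np.ones(spec.n_forms),
                                               size=spec.n_categories))

    if spec.production_cv > 0:
        sigma = np.sqrt(np.log1p(spec.production_cv ** 2))
        samples = rng.lognormal(np.log(spec.production_median_t), sigma,
                                size=(len(years), spec.n_runs))
    else:
        samples = np.full((len(years), spec.n_runs), spec.production_median_t)
    production = ProductionSeries(years, samples)

    priors = []
    for source, targets in TOY_SPLITS.items():
        for target, tc in targets.items():
            if spec.tc_spread > 0 and 0 < tc < 1:
                lo = max(0.0, tc - spec.tc_spread)
                hi = min(1.0, tc + spec.tc_spread)
                priors.append(TransferCoefficientPrior((source, target),
                                                       "triangular", (lo, tc, hi)))
            else:
                priors.append(TransferCoefficientPrior((source, target),
                                                       "point", (tc,)))
    schedules = {}
    if spec.use_release_fraction < 1:
        r = spec.use_release_fraction
        fractions = [r * (1 - r) ** k for k in range(spec.horizon_years)]
        schedules["use"] = ReleaseSchedule("use", tuple(fractions))

    scenario = Scenario(toy_graph(), priors,
                        {"production": production}, schedules)
    expected_sinks = expected_sink_masses(spec)
    return ScenarioBundle(scenario, E, F, production, expected_sinks, spec)


def expected_sink_masses(spec: SyntheticScenarioSpec) -> dict[str, float]:
    """Closed-form expected terminal masses of the toy graph at end of horizon.

    With production mean P per year over Y years and geometric yearly
    release fraction r from the in-use stock, the mass released by year
    Y from a cohort entering in year y is 1 - (1-r)^(Y-y+1); summing the
    geometric series gives the released total, which splits over the
    terminal compartments by the nominal path coefficients.
    """
    mean_production = spec.production_median_t
    if spec.production_cv > 0:
        sigma2 = np.log1p(spec.production_cv ** 2)
        mean_production = spec.production_median_t * np.exp(sigma2 / 2)
    Y, r = spec.horizon_years, spec.use_release_fraction
    if r == 1:
        released = mean_production * Y
    else:
        # sum over entry years of (1 - (1-r)^(age+1))
        ages = np.arange(Y)
        released = mean_production * float(np.sum(1 - (1 - r) ** (ages + 1)))
    splits = TOY_SPLITS["use"]
    return {
        "landfill": released * splits["landfill"],
        "elimination": released * splits["elimination"],
        "natural_soil": released * splits["air"],
        "surface_water": released * splits["wwtp"] * TOY_SPLITS["wwtp"]["surface_water"],
        "sludge_soil": released * splits["wwtp"] * TOY_SPLITS["wwtp"]["sludge_soil"],
    }


@dataclass
class HazardBundle:
    """make_hazard_dataset output: records plus the analytic ground truth."""

    records: list[ToxicityRecord]
    true_hc5_mg_L: float
    true_species_sensitivities: dict[str, float]
    n_species: int
    spec: SyntheticHazardSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


# default uncertainty factors used when emitting acute records, matching
# the shipped UncertaintyFactorTable so conversion round-trips exactly
_ACUTE_UF = {"ECx": 10.0 * 10.0, "LCx": 10.0 * 10.0}


def make_hazard_dataset(spec: SyntheticHazardSpec) -> HazardBundle:
    """Toxicity table from a lognormal species-sensitivity law.

    The analytic truth is the 5% quantile of the law,
    ``exp(mu + sigma * z_0.05)``; it depends only on (mu, sigma), never
    on the seed.  Endpoint counts per species are one each plus a
    multinomial split of the remainder, so the default spec reproduces
    the real inventory's shape (113 records over 26 species).
    """
    rng = np.random.default_rng(spec.seed)
    z05 = stats.norm.ppf(0.05)
    true_hc5 = float(np.exp(spec.mu + spec.sigma * z05))

    log_sens = rng.normal(spec.mu, spec.sigma, spec.n_species)
    extra = rng.multinomial(spec.endpoints_total - spec.n_species,
                            np.full(spec.n_species, 1 / spec.n_species))
    counts = extra + 1

    groups = spec.groups
    records: list[ToxicityRecord] = []
    truths: dict[str, float] = {}
    for i in range(spec.n_species):
        name = f"{spec.species_prefix}_{i + 1:03d}"
        truths[name] = float(np.exp(log_sens[i]))
        group = groups[i % len(groups)]
        for j in range(counts[i]):
            chronic = float(np.exp(log_sens[i]
                                   + rng.normal(0, spec.sigma_within)))
            kind = rng.choice(3, p=spec.descriptor_mix)
            if kind == 0:
                descriptor, regime, value = "NOEC", "chronic", chronic
            elif kind == 1:
                descriptor, regime = "ECx", "acute"
                value = chronic * _ACUTE_UF["ECx"]
            else:
                descriptor, regime = "LCx", "acute"
                value = chronic * _ACUTE_UF["LCx"]
            records.append(ToxicityRecord(name, group, spec.form, descriptor,
                                          regime, value,
                                          source=f"synthetic:{spec.seed}"))
    return HazardBundle(records, true_hc5, truths, spec.n_species, spec)


#: Per-form shapes of the default synthetic toxicity inventory: record and
#: species counts mirror the real data inventory (113 aquatic endpoints over
#: 26 species, dominated by graphene oxide, with only five reduced-graphene-
#: oxide records from species sets lacking fish and daphnids).
DEFAULT_FORM_HAZARD_SHAPES: dict[str, dict] = {
    "pG": {"n_species": 9, "endpoints_total": 26},
    "GO": {"n_species": 18, "endpoints_total": 82},
    "rGO": {"n_species": 5, "endpoints_total": 5,
            "groups": ("algae", "plant", "other")},
}


def make_form_hazard_datasets(seed: int = 0, mu: float = 0.0,
                              sigma: float = 0.5,
                              shapes: dict[str, dict] | None = None,
                              ) -> dict[str, HazardBundle]:
    """Per-form hazard bundles whose pooled table matches the real inventory
    shape; each form draws from the same lognormal sensitivity law."""
    shapes = shapes if shapes is not None else DEFAULT_FORM_HAZARD_SHAPES
    bundles = {}
    for i, (form, shape) in enumerate(shapes.items()):
        spec = SyntheticHazardSpec(mu=mu, sigma=sigma, form=form,
                                   species_prefix=f"{form}_species",
                                   seed=seed + 1000 * i, **shape)
        bundles[form] = make_hazard_dataset(spec)
    return bundles
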