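"""Predicted environmental concentrations (PEC) from annual releases.

Freshwater PECs divide the annual release mass into European surface
waters by the freshwater compartment volume (surface area x mean
depth); an alternative mode additionally scales by the hydraulic
residence time of water (default 40 days, the regulatory
recommendation) over the year.  Soil PECs divide the mass reaching the
soil compartment by the receiving soil mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

from .errors import GbmRiskError, UnitError
from .shares import ProductionSeries
from . import units

PEC_MODES = ("annual_dilution", "residence_scaled")


@dataclass(frozen=True)
class EnvironmentalCompartmentSpec:
    """Receiving-compartment dimensions for the PEC formulas.

    freshwater_volume_L
        Total volume of the freshwater compartment in litres.
    residence_time_days
        Hydraulic residence time of water, days (default 40).
    soil_mass_natural_urban_kg, soil_mass_sludge_treated_kg
        Masses of the two soil categories, kilograms.
    """

    freshwater_volume_L: float
    residence_time_days: float = 40.0
    soil_mass_natural_urban_kg: float | None = None
    soil_mass_sludge_treated_kg: float | None = None

    def __post_init__(self):
        if self.freshwater_volume_L <= 0:
            raise GbmRiskError("freshwater volume must be positive")
        if not 0 < self.residence_time_days <= 365:
            raise GbmRiskError("residence time must be in (0, 365] days")
        for m in (self.soil_mass_natural_urban_kg, self.soil_mass_sludge_treated_kg):
            if m is not None and m <= 0:
                raise GbmRiskError("soil masses must be positive")


@dataclass
class ConcentrationDistribution:
    """Monte-Carlo samples of an environmental concentration with a unit."""

    samples: np.ndarray
    unit: str

    def __post_init__(self):
        self.samples = np.atleast_1d(np.asarray(self.samples, dtype=float))
        self.unit = units.canonical(self.unit)
        if np.any(self.samples < 0):
            raise GbmRiskError("concentrations must be non-negative")

    def to(self, unit: str) -> "ConcentrationDistribution":
        factor = units.conversion_factor(self.unit, unit)
        return ConcentrationDistribution(self.samples * factor, unit)

    def mean(self) -> float:
        return float(self.samples.mean())


@dataclass(frozen=True)
class DistributionSummary:
    """Mean, SD and the quantiles reported in the study figures."""

    mean: float
    sd: float
    q05: float
    q25: float
    q75: float
    q95: float
    unit: str = ""

    def __post_init__(self):
        if not (self.q05 <= self.q25 <= self.q75 <= self.q95):
            raise GbmRiskError("quantiles out of order")
        if self.sd < 0:
            raise GbmRiskError("sd must be non-negative")


def pec_freshwater(release: ProductionSeries | np.ndarray | Sequence[float],
                   spec: EnvironmentalCompartmentSpec,
                   mode: str = "annual_dilution",
                   year=None) -> ConcentrationDistribution:
    """Freshwater PEC (ng/L) from an annual release in tonnes/year.

    ``annual_dilution`` (default): C = mass / volume.  ``residence_scaled``:
    C = (mass / volume) * residence_days / 365, accounting for how long
    water (and suspended material) stays in the compartment before
    flowing out.  Applied sample-wise over the Monte-Carlo ensemble.
    """
    if mode not in PEC_MODES:
        raise GbmRiskError(f"unknown PEC mode {mode!r}; choose from {PEC_MODES}")
    mass_t = _release_samples(release, year)
    conc = mass_t * units.NG_PER_TONNE / spec.freshwater_volume_L
    if mode == "residence_scaled":
        conc = conc * spec.residence_time_days / 365.0
    return ConcentrationDistribution(conc, "ng/L")


def pec_soil(mass: ProductionSeries | np.ndarray | Sequence[float],
             soil_mass_kg: float, unit: str = "ng/kg",
             year=None) -> ConcentrationDistribution:
    """Soil PEC: mass (tonnes) over receiving soil mass (kg).

    The caller chooses whether ``mass`` is an annual inflow or an
    accumulated sink mass, and the reporting unit (ng/kg for natural and
    urban soil, ug/kg for sludge-treated soil by convention).
    """
    if soil_mass_kg <= 0:
        raise GbmRiskError("soil mass must be positive")
    if units.family(unit) != "per_mass":
        raise UnitError(f"soil PEC unit must be per kg, got {unit!r}")
    mass_t = _release_samples(mass, year)
    conc_ng_kg = mass_t * units.NG_PER_TONNE / soil_mass_kg
    return ConcentrationDistribution(conc_ng_kg, "ng/kg").to(unit)


def summarize(dist: ConcentrationDistribution) -> DistributionSummary:
    """Empirical mean, SD and Q5/Q25/Q75/Q95 (linear-interpolation quantiles)."""
    x = dist.samples
    if x.size < 2:
        raise GbmRiskError("need at least two samples to summarise")
    q05, q25, q75, q95 = np.percentile(x, [5, 25, 75, 95])
    return DistributionSummary(float(x.mean()), float(x.std(ddof=1)),
                               float(q05), float(q25), float(q75), float(q95),
                               unit=dist.unit)


def round_report(x: float) -> float:
    """Reported rounding: 2 significant figures below 100, 3 at or above.

    Half-up rounding, matching how the study's figures print means and
    quartiles (e.g. 46.23 -> 46, 1040.4 -> 1040, 1.39 -> 1.4).
    """
    if x == 0:
        return 0.0
    sig = 2 if abs(x) < 100 else 3
    d = Decimal(repr(float(abs(x))))
    exponent = d.adjusted() - (sig - 1)
    q = d.quantize(Decimal(1).scaleb(exponent), rounding=ROUND_HALF_UP)
    return float(q) * (1 if x > 0 else -1)


def format_report(x: float) -> str:
    """String form of :func:`round_report` without scientific notation."""
    r = round_report(x)
    if r == int(r) and abs(r) >= 1:
        return str(int(r))
    return repr(r)


def _release_samples(release, year) -> np.ndarray:
    if isinstance(release, ProductionSeries):
        if year is not None:
            return release.for_year(year)
        if len(release.years) == 1:
            return release.samples[0]
        raise GbmRiskError("multi-year series: specify the assessment year")
    arr = np.atleast_1d(np.asarray(release, dtype=float))
    if np.any(arr < 0):
        raise GbmRiskError("release masses must be non-negative")
    return arr
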