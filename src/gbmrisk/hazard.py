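"""Hazard assessment: probabilistic species sensitivity distributions.

Ecotoxicity endpoints collected from the literature come as assorted
dose descriptors (NOEC, LOEC, HONEC, ECx, LCx) under acute or chronic
exposure.  Each record is converted to a chronic NOEC by dividing by
uncertainty factors for exposure duration (UF_t) and dose-descriptor
conversion (UF_dd), grouped per species, and the species sensitivity
distribution is sampled by Monte Carlo: each iteration draws one
endpoint per species and takes the 5th percentile (HC5) of the drawn
values; the mean of the HC5 samples is the probabilistic PNEC.  When
the data are too sparse or taxonomically narrow for an SSD, the
deterministic fallback divides the most sensitive endpoint by an
assessment factor (up to 1,000).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import HazardDataError

DESCRIPTORS = ("NOEC", "LOEC", "HONEC", "ECx", "LCx")
REGIMES = ("acute", "chronic")
GROUPS = ("fish", "algae", "daphnid", "amphibian", "plant", "other")

#: Fraction of species affected at the hazardous concentration.
HC_PERCENTILE = 5.0


@dataclass(frozen=True)
class ToxicityRecord:
    """One aquatic ecotoxicity endpoint for one species."""

    species: str
    group: str
    form: str
    descriptor: str
    regime: str
    value_mg_L: float
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "descriptor", canonical_descriptor(self.descriptor))
        if self.regime not in REGIMES:
            raise HazardDataError(f"unknown exposure regime {self.regime!r}")
        if self.group not in GROUPS:
            raise HazardDataError(f"unknown taxon group {self.group!r}")
        if not self.value_mg_L > 0:
            raise HazardDataError(f"endpoint value must be > 0, got {self.value_mg_L}")


def canonical_descriptor(descriptor: str) -> str:
    """Normalise e.g. 'EC50'/'LC10' to the ECx/LCx descriptor classes."""
    d = descriptor.strip()
    if d in DESCRIPTORS:
        return d
    if re.fullmatch(r"EC\d+", d):
        return "ECx"
    if re.fullmatch(r"LC\d+", d):
        return "LCx"
    raise HazardDataError(
        f"unknown dose descriptor {descriptor!r}; expected one of {DESCRIPTORS}")


@dataclass(frozen=True)
class UncertaintyFactorTable:
    """Divisors converting endpoints to chronic NOECs.

    The shipped defaults (acute -> chronic: 10; EC/LC -> NOEC: 10;
    LOEC -> NOEC: 2.5; HONEC -> NOEC: 1) follow common regulatory
    extrapolation practice and are fully overridable; a chronic NOEC
    passes through with both factors equal to 1.
    """

    uf_t: Mapping[str, float] = field(
        default_factory=lambda: {"chronic": 1.0, "acute": 10.0})
    uf_dd: Mapping[str, float] = field(
        default_factory=lambda: {"NOEC": 1.0, "HONEC": 1.0, "LOEC": 2.5,
                                 "ECx": 10.0, "LCx": 10.0})

    def __post_init__(self):
        for name, table in (("uf_t", self.uf_t), ("uf_dd", self.uf_dd)):
            if any(v < 1 for v in table.values()):
                raise HazardDataError(f"{name} factors must be >= 1")
        if self.uf_t.get("chronic") != 1.0 or self.uf_dd.get("NOEC") != 1.0:
            raise HazardDataError("chronic NOEC must map to unit factors")


@dataclass(frozen=True)
class SpeciesSensitivity:
    """Per-species set of converted chronic NOECs (mg/L)."""

    species: str
    chronic_noecs: tuple[float, ...]
    group: str = "other"

    def __post_init__(self):
        vals = tuple(float(v) for v in self.chronic_noecs)
        object.__setattr__(self, "chronic_noecs", vals)
        if not vals:
            raise HazardDataError(f"species {self.species!r} has no endpoints")
        if any(v <= 0 for v in vals):
            raise HazardDataError(f"species {self.species!r} has non-positive NOECs")


@dataclass
class SSDResult:
    """Monte-Carlo HC5 samples and the derived PNEC point statistics."""

    hc5_samples: np.ndarray  # mg/L
    n_iterations: int
    seed: object
    n_species: int
    mode: str = "resample"
    unit: str = "mg/L"

    @property
    def pnec_point(self) -> float:
        """Mean of the HC5 distribution (the reported PNEC)."""
        return float(self.hc5_samples.mean())

    @property
    def pnec_median(self) -> float:
        return float(np.median(self.hc5_samples))

    def summary(self) -> pd.Series:
        q05, q25, q75, q95 = np.percentile(self.hc5_samples, [5, 25, 75, 95])
        return pd.Series({
            "n_species": self.n_species, "n_iterations": self.n_iterations,
            "mode": self.mode, "unit": self.unit,
            "pnec_mean": self.pnec_point, "pnec_median": self.pnec_median,
            "hc5_sd": float(self.hc5_samples.std(ddof=1)),
            "hc5_q05": float(q05), "hc5_q25": float(q25),
            "hc5_q75": float(q75), "hc5_q95": float(q95),
        })


def to_chronic_noec(record: ToxicityRecord,
                    uf_table: UncertaintyFactorTable | None = None) -> float:
    """Chronic NOEC (mg/L): endpoint value / (UF_t * UF_dd)."""
    uf_table = uf_table or UncertaintyFactorTable()
    if record.regime not in uf_table.uf_t:
        raise HazardDataError(f"no duration factor for regime {record.regime!r}")
    if record.descriptor not in uf_table.uf_dd:
        raise HazardDataError(f"no descriptor factor for {record.descriptor!r}")
    return record.value_mg_L / (uf_table.uf_t[record.regime]
                                * uf_table.uf_dd[record.descriptor])


def build_species_sets(records: Iterable[ToxicityRecord],
                       form: str | None = None,
                       uf_table: UncertaintyFactorTable | None = None,
                       ) -> list[SpeciesSensitivity]:
    """Convert and group records into per-species chronic-NOEC sets.

    ``form`` filters records to one material form; None keeps all forms
    (the pooled assessment across the material family).
    """
    records = list(records)
    if form is not None:
        kept = [r for r in records if r.form == form]
        if not kept:
            forms = sorted({r.form for r in records})
            raise HazardDataError(
                f"no toxicity records for form {form!r}; available forms: {forms}")
        records = kept
    if not records:
        raise HazardDataError("no toxicity records supplied")
    by_species: dict[str, list[ToxicityRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    sets = []
    for species, recs in by_species.items():
        noecs = tuple(to_chronic_noec(r, uf_table) for r in recs)
        groups = [r.group for r in recs]
        group = max(set(groups), key=groups.count)
        sets.append(SpeciesSensitivity(species, noecs, group))
    return sets


def estimate_hc5(species_sets: Sequence[SpeciesSensitivity],
                 n_iterations: int = 10_000, seed=None,
                 mode: str = "resample") -> SSDResult:
    """Monte-Carlo HC5 distribution over the species sensitivity sets.

    ``resample`` (default): each iteration draws one endpoint uniformly
    from every species' set and takes the 5th percentile (linear
    interpolation) of the per-species draws.  ``most_sensitive``: each
    species is represented by its minimum endpoint, so every iteration
    is identical and the HC5 distribution is degenerate.
    """
    if n_iterations < 1:
        raise HazardDataError("n_iterations must be >= 1")
    if not species_sets:
        raise HazardDataError("need at least one species set")
    if mode not in ("resample", "most_sensitive"):
        raise HazardDataError(f"unknown SSD mode {mode!r}")
    rng = np.random.default_rng(seed)
    n_sp = len(species_sets)
    if mode == "most_sensitive":
        vals = np.array([min(s.chronic_noecs) for s in species_sets])
        hc5 = np.full(n_iterations, np.percentile(vals, HC_PERCENTILE))
    else:
        cols = []
        for s in species_sets:
            vals = np.asarray(s.chronic_noecs)
            idx = rng.integers(0, vals.size, n_iterations)
            cols.append(vals[idx])
        sampled = np.column_stack(cols)  # (n_iterations, n_species)
        hc5 = np.percentile(sampled, HC_PERCENTILE, axis=1)
    return SSDResult(hc5, n_iterations, seed, n_sp, mode=mode)


def pnec_af(records: Iterable[ToxicityRecord], assessment_factor: float = 1000.0,
            uf_table: UncertaintyFactorTable | None = None, *,
            convert: bool = False) -> tuple[float, ToxicityRecord]:
    """Deterministic PNEC: most sensitive endpoint / assessment factor.

    Returns (PNEC in mg/L, the minimum record).  By default the raw
    endpoint values are compared (the assessment factor already covers
    extrapolation); set ``convert=True`` to apply the UF conversion
    before taking the minimum.
    """
    records = list(records)
    if not records:
        raise HazardDataError("no toxicity records supplied")
    if assessment_factor < 1:
        raise HazardDataError("assessment factor must be >= 1")
    key = ((lambda r: to_chronic_noec(r, uf_table)) if convert
           else (lambda r: r.value_mg_L))
    lowest = min(records, key=key)
    return key(lowest) / assessment_factor, lowest


@dataclass(frozen=True)
class PnecStrategyDecision:
    strategy: str  # "pssd" | "assessment_factor"
    rationale: str
    n_species: int
    groups_present: tuple[str, ...]


def choose_pnec_strategy(species_sets: Sequence[SpeciesSensitivity],
                         min_species: int = 8,
                         required_groups: Sequence[str] = ("fish", "daphnid", "algae"),
                         ) -> PnecStrategyDecision:
    """PSSD when species coverage is statistically and taxonomically adequate.

    The probabilistic route needs at least ``min_species`` species and
    every required trophic group represented; otherwise the
    assessment-factor fallback is selected.
    """
    if not species_sets:
        raise HazardDataError("no species sets; build them first")
    groups = tuple(sorted({s.group for s in species_sets}))
    n = len(species_sets)
    missing = [g for g in required_groups if g not in groups]
    if n >= min_species and not missing:
        return PnecStrategyDecision(
            "pssd", f"{n} species covering {groups}: sufficient for a PSSD",
            n, groups)
    reasons = []
    if n < min_species:
        reasons.append(f"only {n} species (< {min_species})")
    if missing:
        reasons.append(f"missing trophic groups {missing}")
    return PnecStrategyDecision(
        "assessment_factor", "; ".join(reasons) + ": falling back to the "
        "assessment-factor approach", n, groups)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["species", "group", "form", "descriptor", "regime",
               "value_mg_L", "source"]


def records_to_csv(records: Iterable[ToxicityRecord], path) -> None:
    # %.17g keeps endpoint values exact across a write/read round trip
    pd.DataFrame([r.__dict__ for r in records])[CSV_COLUMNS].to_csv(
        path, index=False, float_format="%.17g")


def records_from_csv(path) -> list[ToxicityRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise HazardDataError(f"toxicity CSV lacks columns {missing}")
    if "source" not in df.columns:
        df["source"] = ""
    df["source"] = df["source"].fillna("")
    return [ToxicityRecord(r.species, r.group, r.form, r.descriptor, r.regime,
                           float(r.value_mg_L), str(r.source))
            for r in df.itertuples()]


def ssd_curve(species_sets: Sequence[SpeciesSensitivity]) -> pd.DataFrame:
    """Species rank vs geometric-mean chronic NOEC, for SSD curve plots."""
    gm = {s.species: float(np.exp(np.mean(np.log(s.chronic_noecs))))
          for s in species_sets}
    df = pd.DataFrame(sorted(gm.items(), key=lambda kv: kv[1]),
                      columns=["species", "noec_mg_L"])
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["affected_fraction"] = df["rank"] / (n + 1)
    return df
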