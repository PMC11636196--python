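"""End-to-end orchestration: disaggregate -> simulate -> PEC -> PNEC -> RCR.

A single :class:`RunConfig` names the input files and modelling
choices; :func:`run_era` executes one seeded assessment and writes a
machine-readable summary plus tidy CSV tables.  A root seed is expanded
into per-stage substreams (production sampling, per-form simulations,
SSD Monte Carlo, RCR resampling) so stages can be re-run independently
with stable randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as scenario_io
from .dpmfa import Scenario, mass_balance_report, run_simulation
from .errors import GbmRiskError
from .exposure import (EnvironmentalCompartmentSpec, pec_freshwater,
                       round_report, summarize)
from .hazard import (build_species_sets, choose_pnec_strategy, estimate_hc5,
                     pnec_af, records_from_csv, UncertaintyFactorTable)
from .risk import exceedance_probability, orders_below_one, rcr_distribution
from .shares import (ProductionSeries, ShareMatrix, allocate_form_production,
                     compose_form_shares, default_form_split_matrix)

TOTAL_LABEL = "GBM"


@dataclass
class RunConfig:
    """Validated configuration for one assessment run."""

    scenario: str
    hazard: str
    e_matrix: str | None = None
    f_matrix: str | None = None
    n_runs: int = 10_000
    n_iterations: int = 10_000
    seed: int = 0
    pec_mode: str = "annual_dilution"
    freshwater_volume_L: float = 1e15
    residence_time_days: float = 40.0
    soil_compartments: dict = field(default_factory=dict)
    inflow_compartment: str = "production"
    pec_compartment: str = "surface_water"
    assessment_year: int | None = None
    assessment_factor: float = 1000.0
    min_species: int = 8
    required_groups: tuple = ("fish", "daphnid", "algae")
    outdir: str = "era_output"

    def __post_init__(self):
        # pyyaml reads "1.0e15" as a string; coerce numerics defensively
        for name in ("freshwater_volume_L", "residence_time_days",
                     "assessment_factor"):
            setattr(self, name, float(getattr(self, name)))
        self.n_runs, self.n_iterations = int(self.n_runs), int(self.n_iterations)
        if self.n_runs < 1 or self.n_iterations < 1:
            raise GbmRiskError("n_runs and n_iterations must be >= 1")
        self.seed = int(self.seed)
        for name in ("scenario", "hazard"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise GbmRiskError(f"{name} file {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise GbmRiskError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _substreams(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def disaggregate(E: ShareMatrix, F: ShareMatrix,
                 production: ProductionSeries) -> dict[str, ProductionSeries]:
    """Per-form production series from total production and E, F."""
    G = compose_form_shares(E, F)
    return {form: allocate_form_production(production, G, form)
            for form in F.col_labels}


def run_era(config: RunConfig, log=print) -> dict:
    """One full seeded assessment; returns (and writes) the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = _substreams(config.seed, 4)
    s_prod, s_sim, s_ssd, s_rcr = streams

    scenario = scenario_io.load_scenario(config.scenario, config.n_runs, s_prod)
    F = (ShareMatrix.from_csv(config.f_matrix) if config.f_matrix
         else default_form_split_matrix())
    if config.e_matrix:
        E = ShareMatrix.from_csv(config.e_matrix)
    else:
        raise GbmRiskError("an E matrix (year x category market shares) is required")
    production = scenario.inflows[config.inflow_compartment]
    log(f"[disaggregate] {len(F.col_labels)} forms x {len(E.col_labels)} categories")
    per_form = disaggregate(E, F, production)

    env = EnvironmentalCompartmentSpec(
        freshwater_volume_L=config.freshwater_volume_L,
        residence_time_days=config.residence_time_days)
    year = config.assessment_year or scenario.years[-1]
    sim_streams = _substreams(int(s_sim.generate_state(1)[0] % 2**31),
                              len(per_form) + 1)

    records = records_from_csv(config.hazard)
    uf = UncertaintyFactorTable()
    log(f"[hazard] {len(records)} records; UF table {uf.uf_t} / {uf.uf_dd}; "
        f"PEC mode {config.pec_mode!r}")

    rows, rcr_samples = [], {}
    labels = [TOTAL_LABEL] + list(per_form)
    for i, label in enumerate(labels):
        series = production if label == TOTAL_LABEL else per_form[label]
        sc = Scenario(scenario.graph, scenario.priors,
                      {config.inflow_compartment: series}, scenario.schedules)
        ens = run_simulation(sc, config.n_runs, sim_streams[i])
        balance = mass_balance_report(ens)["relative_residual"].abs().max()
        release = ens.inflow_to(config.pec_compartment)[:, list(ens.years).index(year)]
        pec = pec_freshwater(release, env, mode=config.pec_mode)
        pec_sum = summarize(pec)

        form_filter = None if label == TOTAL_LABEL else label
        try:
            sets = build_species_sets(records, form_filter, uf)
        except GbmRiskError as exc:
            log(f"[hazard] {label}: {exc}")
            sets = []
        if sets:
            decision = choose_pnec_strategy(sets, config.min_species,
                                            config.required_groups)
        else:
            decision = None
        if decision is None:
            log(f"[pnec] {label}: no toxicity records; skipping PNEC and RCR")
            rows.append({"form": label, "year": year,
                         "pec_mean_ng_L": pec_sum.mean,
                         "pec_sd_ng_L": pec_sum.sd,
                         "pec_q05_ng_L": pec_sum.q05,
                         "pec_q95_ng_L": pec_sum.q95,
                         "pec_mean_rounded": round_report(pec_sum.mean),
                         "pnec_mg_L": None, "pnec_strategy": None,
                         "rcr_mean": None, "rcr_q25": None, "rcr_q75": None,
                         "p_rcr_above_1": None, "orders_below_one": None,
                         "max_mass_balance_residual": float(balance)})
            continue
        if decision.strategy == "pssd":
            ssd = estimate_hc5(sets, config.n_iterations,
                               np.random.default_rng(s_ssd.spawn(1)[0]),
                               mode="resample")
            pnec, pnec_desc = ssd, f"PSSD mean HC5 = {ssd.pnec_point:.4g} mg/L"
        else:
            recs = [r for r in records
                    if form_filter is None or r.form == form_filter]
            pnec_value, lowest = pnec_af(recs, config.assessment_factor)
            pnec = pnec_value
            pnec_desc = (f"AF: {lowest.value_mg_L:g} mg/L ({lowest.species}) "
                         f"/ {config.assessment_factor:g}")
        log(f"[pnec] {label}: {decision.strategy} - {pnec_desc}")

        rcr = rcr_distribution(pec, pnec,
                               seed=np.random.default_rng(s_rcr.spawn(1)[0]))
        rcr_samples[label] = rcr.samples
        rows.append({
            "form": label, "year": year,
            "pec_mean_ng_L": pec_sum.mean, "pec_sd_ng_L": pec_sum.sd,
            "pec_q05_ng_L": pec_sum.q05, "pec_q95_ng_L": pec_sum.q95,
            "pec_mean_rounded": round_report(pec_sum.mean),
            "pnec_mg_L": (pnec.pnec_point if hasattr(pnec, "pnec_point")
                          else pnec),
            "pnec_strategy": decision.strategy if decision else "assessment_factor",
            "rcr_mean": rcr.mean(),
            "rcr_q25": float(np.percentile(rcr.samples, 25)),
            "rcr_q75": float(np.percentile(rcr.samples, 75)),
            "p_rcr_above_1": exceedance_probability(rcr),
            "orders_below_one": orders_below_one(rcr.mean()),
            "max_mass_balance_residual": float(balance),
        })

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "era_summary.csv", index=False)
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_runs": config.n_runs,
        "n_iterations": config.n_iterations,
        "pec_mode": config.pec_mode,
        "units": {"pec": "ng/L", "pnec": "mg/L", "rcr": "dimensionless"},
        "forms": {r["form"]: {k: v for k, v in r.items() if k != "form"}
                  for r in rows},
    }
    with open(outdir / "era_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log(f"[done] wrote {outdir / 'era_summary.json'}")
    return summary
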