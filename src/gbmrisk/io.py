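"""Scenario (de)serialisation: YAML compartment graphs, priors and inflows.

A scenario file declares compartments, edges with transfer-coefficient
priors, release schedules, and per-compartment inflow laws; production
samples are drawn at load time for a requested number of Monte-Carlo
runs, so the file itself stays small and text-only.

Example::

    years: {start: 2021, n: 10}
    compartments:
      - {name: production, kind: technical}
      - {name: landfill, kind: sink}
    edges:
      - {source: production, target: landfill, distribution: point, params: [1.0]}
    inflows:
      production: {law: lognormal, median_t: 1000, cv: 0.5}
    schedules: {}
"""

from __future__ import annotations

import numpy as np
import yaml

from .dpmfa import (Compartment, CompartmentGraph, ReleaseSchedule, Scenario,
                    TransferCoefficientPrior)
from .errors import GbmRiskError
from .shares import ProductionSeries


def scenario_to_dict(scenario: Scenario,
                     inflow_laws: dict | None = None) -> dict:
    """YAML-ready dict; ``inflow_laws`` overrides sampled inflows with laws."""
    d = {
        "years": {"start": int(scenario.years[0]), "n": len(scenario.years)},
        "compartments": [{"name": c.name, "kind": c.kind}
                         for c in scenario.graph.compartments],
        "edges": [{"source": p.edge[0], "target": p.edge[1],
                   "distribution": p.distribution, "params": list(p.params)}
                  for p in scenario.priors],
        "schedules": {name: list(s.fractions)
                      for name, s in scenario.schedules.items()},
    }
    if inflow_laws is not None:
        d["inflows"] = inflow_laws
    else:
        d["inflows"] = {comp: {"law": "point",
                               "masses_t": [float(np.mean(s)) for s in series.samples]}
                        for comp, series in scenario.inflows.items()}
    return d


def save_scenario(scenario: Scenario, path, inflow_laws: dict | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario, inflow_laws), fh,
                       sort_keys=False)


def _sample_inflow(law: dict, years, n_runs: int,
                   rng: np.random.Generator) -> ProductionSeries:
    kind = law.get("law", "point")
    n_years = len(years)
    if kind == "point":
        masses = law.get("masses_t", law.get("mass_t"))
        masses = np.broadcast_to(np.asarray(masses, float), (n_years,))
        return ProductionSeries(years, np.repeat(masses[:, None], n_runs, axis=1))
    if kind == "lognormal":
        median = np.broadcast_to(np.asarray(law["median_t"], float), (n_years,))
        cv = float(law.get("cv", 0.0))
        if cv <= 0:
            return ProductionSeries(years, np.repeat(median[:, None], n_runs, axis=1))
        sigma = np.sqrt(np.log1p(cv ** 2))
        samples = rng.lognormal(np.log(median)[:, None], sigma,
                                size=(n_years, n_runs))
        return ProductionSeries(years, samples)
    raise GbmRiskError(f"unknown inflow law {kind!r}")


def load_scenario(path, n_runs: int, seed=None) -> Scenario:
    """Build a runnable :class:`Scenario`, sampling inflow laws with ``seed``."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("years", "compartments", "edges", "inflows"):
        if key not in d:
            raise GbmRiskError(f"scenario file lacks required key {key!r}")
    y = d["years"]
    years = tuple(range(int(y["start"]), int(y["start"]) + int(y["n"]))) \
        if isinstance(y, dict) else tuple(int(v) for v in y)
    graph = CompartmentGraph(
        [Compartment(c["name"], c.get("kind", "technical"))
         for c in d["compartments"]],
        [(e["source"], e["target"]) for e in d["edges"]],
    )
    priors = [TransferCoefficientPrior((e["source"], e["target"]),
                                       e["distribution"], tuple(e["params"]))
              for e in d["edges"]]
    rng = np.random.default_rng(seed)
    inflows = {comp: _sample_inflow(law, years, n_runs, rng)
               for comp, law in d["inflows"].items()}
    schedules = {name: ReleaseSchedule(name, tuple(fr))
                 for name, fr in (d.get("schedules") or {}).items()}
    return Scenario(graph, priors, inflows, schedules)
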