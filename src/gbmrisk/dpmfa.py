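"""Dynamic probabilistic material-flow simulation.

Masses produced each year are pushed through a directed compartment
graph (manufacturing, use phases, waste treatment, environmental media).
Transfer coefficients — the fractions routing a compartment's annual
throughput to each downstream compartment — are uncertain and sampled
per Monte-Carlo run; in-use compartments may hold stock and release it
over later years according to a release schedule; air is modelled as a
transfer compartment that passes mass through within the year without
accumulating; compartments without outflows (landfill, subsurface,
soils, elimination) accumulate over the whole horizon.

The model's time step is one year: within a year a single topological
pass moves mass through arbitrarily many compartments (e.g. production
-> air -> soil completes in the same year).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import GraphError
from .shares import ProductionSeries

KINDS = ("technical", "environmental", "sink", "transfer", "elimination")
#: kinds that never have outgoing edges and accumulate inflows
TERMINAL_KINDS = ("sink", "elimination")


@dataclass(frozen=True)
class Compartment:
    name: str
    kind: str = "technical"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise GraphError(f"unknown compartment kind {self.kind!r}")


@dataclass
class CompartmentGraph:
    """Directed compartment graph with per-kind structural rules."""

    compartments: Sequence[Compartment]
    edges: Sequence[tuple[str, str]]

    def __post_init__(self):
        self.compartments = [c if isinstance(c, Compartment) else Compartment(*c)
                             for c in self.compartments]
        self.edges = [tuple(e) for e in self.edges]
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise GraphError("duplicate compartment names")
        self._kind = {c.name: c.kind for c in self.compartments}
        known = set(names)
        for s, t in self.edges:
            if s not in known or t not in known:
                raise GraphError(f"edge ({s}, {t}) references unknown compartment")
        self.out_edges: dict[str, list[str]] = {n: [] for n in names}
        for s, t in self.edges:
            self.out_edges[s].append(t)
        for c in self.compartments:
            if c.kind in TERMINAL_KINDS and self.out_edges[c.name]:
                raise GraphError(f"{c.kind} compartment {c.name!r} has outgoing edges")
            if c.kind == "transfer" and not self.out_edges[c.name]:
                raise GraphError(f"transfer compartment {c.name!r} has no outgoing edge")
        self.order = self._toposort()

    def _toposort(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(n for n in self._kind if self._kind[n] not in TERMINAL_KINDS)
        g.add_edges_from((s, t) for s, t in self.edges
                         if self._kind[t] not in TERMINAL_KINDS)
        try:
            return list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            cyc = nx.find_cycle(g)
            raise GraphError(f"cycle among non-sink compartments: {cyc}") from exc

    def kind(self, name: str) -> str:
        return self._kind[name]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    @property
    def terminals(self) -> list[str]:
        """Compartments that accumulate: terminal kinds or no outgoing edges."""
        return [c.name for c in self.compartments
                if c.kind in TERMINAL_KINDS or not self.out_edges[c.name]]


@dataclass(frozen=True)
class TransferCoefficientPrior:
    """Prior on one edge's transfer coefficient.

    ``distribution`` is one of ``point(v)``, ``uniform(lo, hi)``,
    ``triangular(lo, mode, hi)``; all parameters lie in [0, 1].
    """

    edge: tuple[str, str]
    distribution: str
    params: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "edge", tuple(self.edge))
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        n_expected = {"point": 1, "uniform": 2, "triangular": 3}
        if self.distribution not in n_expected:
            raise GraphError(f"unknown TC distribution {self.distribution!r}")
        if len(self.params) != n_expected[self.distribution]:
            raise GraphError(f"{self.distribution} prior needs "
                             f"{n_expected[self.distribution]} parameters")
        if any(not 0 <= p <= 1 for p in self.params):
            raise GraphError(f"TC prior parameters {self.params} outside [0, 1]")
        if list(self.params) != sorted(self.params):
            raise GraphError(f"TC prior parameters must be ordered, got {self.params}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.distribution == "point":
            return np.full(size, self.params[0])
        if self.distribution == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size) if hi > lo else np.full(size, lo)
        lo, mode, hi = self.params
        if hi == lo:
            return np.full(size, lo)
        return rng.triangular(lo, mode, hi, size)


@dataclass(frozen=True)
class ReleaseSchedule:
    """Fractions of entering mass released 0, 1, 2, ... years after entry.

    The cumulative sum may be below 1; the remainder stays in stock for
    the rest of the horizon.  A compartment with no schedule releases
    everything immediately (fraction 1 at lag 0).
    """

    category: str
    fractions: tuple[float, ...]

    def __post_init__(self):
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if any(f < 0 for f in fr):
            raise GraphError("release fractions must be non-negative")
        if sum(fr) > 1 + 1e-12:
            raise GraphError(f"release fractions sum to {sum(fr)} > 1")

    def fraction_at(self, lag: int) -> float:
        return self.fractions[lag] if 0 <= lag < len(self.fractions) else 0.0


@dataclass
class Scenario:
    """Complete DPMFA input: graph, TC priors, inflows and schedules.

    ``inflows`` maps receiving compartments to production/release series
    (tonnes/year); ``schedules`` maps in-use compartment names to their
    release schedules.
    """

    graph: CompartmentGraph
    priors: Sequence[TransferCoefficientPrior]
    inflows: Mapping[str, ProductionSeries]
    schedules: Mapping[str, ReleaseSchedule] = field(default_factory=dict)

    def __post_init__(self):
        self.priors = list(self.priors)
        by_source: dict[str, dict[str, TransferCoefficientPrior]] = {}
        for p in self.priors:
            s, t = p.edge
            if t not in self.graph.out_edges.get(s, []):
                raise GraphError(f"prior on edge {p.edge} absent from graph")
            by_source.setdefault(s, {})[t] = p
        for name in self.graph.names:
            targets = self.graph.out_edges[name]
            missing = [t for t in targets if t not in by_source.get(name, {})]
            if targets and missing:
                raise GraphError(
                    f"compartment {name!r} lacks TC priors for edges to {missing}")
        self._priors_by_source = by_source
        for name in self.schedules:
            if name not in self.graph.names:
                raise GraphError(f"schedule for unknown compartment {name!r}")
            if self.graph.kind(name) == "transfer":
                raise GraphError(f"transfer compartment {name!r} cannot hold stock")
        years = None
        for comp, series in self.inflows.items():
            if comp not in self.graph.names:
                raise GraphError(f"inflow into unknown compartment {comp!r}")
            years = series.years if years is None else years
            if series.years != years:
                raise GraphError("all inflow series must share the same years")
        if years is None:
            raise GraphError("scenario has no inflows")
        self.years = years


@dataclass
class FlowEnsemble:
    """Monte-Carlo flows, stocks and accumulated terminal masses (tonnes)."""

    years: tuple
    edge_labels: tuple[tuple[str, str], ...]
    compartments: tuple[str, ...]
    terminals: tuple[str, ...]
    flows: np.ndarray        # (n_runs, n_years, n_edges)
    stocks: np.ndarray       # (n_runs, n_years, n_compartments), end of year
    accumulated: np.ndarray  # (n_runs, n_years, n_terminals), cumulative
    external_inflow: np.ndarray  # (n_runs, n_years), total external entry

    @property
    def n_runs(self) -> int:
        return self.flows.shape[0]

    @property
    def sinks(self) -> dict[str, np.ndarray]:
        """Accumulated mass per terminal compartment at end of horizon, per run."""
        return {name: self.accumulated[:, -1, i]
                for i, name in enumerate(self.terminals)}

    def edge_flow(self, source: str, target: str) -> np.ndarray:
        """Flows on one edge, shape (n_runs, n_years)."""
        return self.flows[:, :, self.edge_labels.index((source, target))]

    def inflow_to(self, compartment: str) -> np.ndarray:
        """Total arriving mass per run and year (sum over incoming edges)."""
        idx = [i for i, (s, t) in enumerate(self.edge_labels) if t == compartment]
        return self.flows[:, :, idx].sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (run, year, source, target, mass_t) table of all flows."""
        n_runs, n_years, n_edges = self.flows.shape
        runs, years, edges = np.meshgrid(
            np.arange(n_runs), np.asarray(self.years), np.arange(n_edges),
            indexing="ij")
        src = np.array([e[0] for e in self.edge_labels])
        tgt = np.array([e[1] for e in self.edge_labels])
        return pd.DataFrame({
            "run": runs.ravel(), "year": years.ravel(),
            "source": src[edges.ravel()], "target": tgt[edges.ravel()],
            "mass_t": self.flows.ravel(),
        })


def sample_transfer_coefficients(priors: Iterable[TransferCoefficientPrior],
                                 seed=None, n_runs: int = 1,
                                 ) -> dict[str, dict[str, np.ndarray]]:
    """Draw per-run transfer coefficients and renormalise per source.

    Each outgoing coefficient is drawn from its prior, then the outgoing
    vector of every source is rescaled to sum to exactly 1 (a point
    prior set that already sums to 1 passes through unchanged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_source: dict[str, dict[str, np.ndarray]] = {}
    for p in priors:
        s, t = p.edge
        by_source.setdefault(s, {})[t] = p.sample(rng, n_runs)
    for s, draws in by_source.items():
        total = np.sum(list(draws.values()), axis=0)
        if np.any(total <= 0):
            raise GraphError(f"all transfer-coefficient draws zero for source {s!r}")
        for t in draws:
            draws[t] = draws[t] / total
    return by_source


def propagate_year(graph: CompartmentGraph,
                   coefficients: Mapping[str, Mapping[str, np.ndarray]],
                   external_inflow: Mapping[str, np.ndarray],
                   stocks: dict[str, dict[int, np.ndarray]],
                   schedules: Mapping[str, ReleaseSchedule],
                   year_index: int = 0,
                   ) -> tuple[dict[tuple[str, str], np.ndarray], dict]:
    """One year of mass propagation; returns (edge flows, updated stock cohorts).

    ``stocks`` maps compartment -> {entry year index -> entered mass};
    the schedule of an in-use compartment decides which fraction of each
    cohort (including this year's inflow, lag 0) is released now.  The
    unreleased remainder stays in the cohort ledger.  Compartments
    without a schedule pass their full throughput downstream; terminal
    compartments accumulate.
    """
    flows: dict[tuple[str, str], np.ndarray] = {}
    arriving: dict[str, np.ndarray] = {}

    def _get(d, key):
        v = d.get(key, 0.0)
        return np.asarray(v, dtype=float)

    for comp in graph.order:
        inflow = _get(external_inflow, comp) + _get(arriving, comp)
        sched = schedules.get(comp)
        if sched is None:
            throughput = inflow
        else:
            cohorts = stocks.setdefault(comp, {})
            cohorts[year_index] = _get(cohorts, year_index) + inflow
            throughput = 0.0
            for entry, mass in cohorts.items():
                rel = sched.fraction_at(year_index - entry)
                if rel:
                    released = np.asarray(mass, dtype=float) * rel / max(
                        1.0 - sum(sched.fraction_at(k)
                                  for k in range(year_index - entry)), 1e-300)
                    # cohorts store REMAINING mass; convert schedule fraction
                    # (of original entry) to a fraction of the remainder
                    cohorts[entry] = np.asarray(mass, dtype=float) - released
                    throughput = throughput + released
            throughput = np.asarray(throughput, dtype=float)
        for target in graph.out_edges[comp]:
            tc = np.asarray(coefficients[comp][target], dtype=float)
            f = throughput * tc
            flows[(comp, target)] = f
            arriving[target] = _get(arriving, target) + f
        if not graph.out_edges[comp]:
            # environmental compartment with no outflow accumulates like a sink
            stocks.setdefault(comp, {})
            stocks[comp][-1] = _get(stocks[comp], -1) + throughput
    for comp in graph.names:
        if graph.kind(comp) in TERMINAL_KINDS:
            total = _get(external_inflow, comp) + _get(arriving, comp)
            stocks.setdefault(comp, {})
            stocks[comp][-1] = _get(stocks[comp], -1) + total
            flows[(comp, "__accumulated__")] = total
    return flows, stocks


def run_simulation(scenario: Scenario, n_runs: int = 10_000, seed=None,
                   ) -> FlowEnsemble:
    """Monte-Carlo DPMFA over the scenario horizon.

    Transfer coefficients are resampled once per run and held fixed
    across years (parameter, not process, uncertainty); production
    samples come from the scenario's inflow series.  Deterministic for a
    given seed.
    """
    if n_runs < 1:
        raise GraphError("n_runs must be >= 1")
    graph = scenario.graph
    some = next(iter(scenario.inflows.values()))
    if some.n_runs not in (1, n_runs):
        raise GraphError(
            f"inflow series carry {some.n_runs} runs but n_runs={n_runs}")
    rng = np.random.default_rng(seed)
    coeffs = sample_transfer_coefficients(scenario.priors, rng, n_runs)

    years = scenario.years
    edge_labels = tuple(scenario.graph.edges)
    comps = tuple(graph.names)
    terminals = tuple(graph.terminals)
    flows = np.zeros((n_runs, len(years), len(edge_labels)))
    stocks_out = np.zeros((n_runs, len(years), len(comps)))
    accumulated = np.zeros((n_runs, len(years), len(terminals)))
    ext_total = np.zeros((n_runs, len(years)))

    cohorts: dict[str, dict[int, np.ndarray]] = {}
    for yi, year in enumerate(years):
        external = {}
        for comp, series in scenario.inflows.items():
            s = series.samples[yi]
            external[comp] = np.broadcast_to(s, (n_runs,)).astype(float) \
                if s.shape != (n_runs,) else s
            ext_total[:, yi] += external[comp]
        year_flows, cohorts = propagate_year(
            graph, coeffs, external, cohorts, scenario.schedules, yi)
        for (s, t), f in year_flows.items():
            if t == "__accumulated__":
                continue
            flows[:, yi, edge_labels.index((s, t))] = f
        for ci, comp in enumerate(comps):
            if comp in cohorts:
                if comp in terminals:
                    accumulated[:, yi, terminals.index(comp)] = sum(
                        np.broadcast_to(m, (n_runs,))
                        for m in cohorts[comp].values())
                else:
                    stocks_out[:, yi, ci] = sum(
                        np.broadcast_to(m, (n_runs,))
                        for m in cohorts[comp].values())
    return FlowEnsemble(tuple(years), edge_labels, comps, terminals,
                        flows, stocks_out, accumulated,
                        np.cumsum(ext_total, axis=1))


def mass_balance_report(ensemble: FlowEnsemble) -> pd.DataFrame:
    """Per-run, per-year conservation residuals relative to cumulative inflow.

    residual = cumulative external inflow - (accumulated terminal masses
    + in-use stocks); relative residual uses the cumulative inflow as
    denominator (0 inflow reports the absolute residual).
    """
    held = ensemble.accumulated.sum(axis=2) + ensemble.stocks.sum(axis=2)
    residual = ensemble.external_inflow - held
    denom = np.where(ensemble.external_inflow > 0, ensemble.external_inflow, 1.0)
    rel = residual / denom
    n_runs, n_years = residual.shape
    runs, yrs = np.meshgrid(np.arange(n_runs), np.asarray(ensemble.years),
                            indexing="ij")
    return pd.DataFrame({"run": runs.ravel(), "year": yrs.ravel(),
                         "residual_t": residual.ravel(),
                         "relative_residual": rel.ravel()})


def sink_distribution_by_form(ensembles: Mapping[str, FlowEnsemble],
                              compartment: str) -> dict[str, float]:
    """Mean accumulated mass shares per form in one terminal compartment."""
    means = {}
    for form, ens in ensembles.items():
        if compartment not in ens.terminals:
            raise GraphError(f"{compartment!r} is not a terminal compartment")
        means[form] = float(ens.sinks[compartment].mean())
    total = sum(means.values())
    if total <= 0:
        raise GraphError(f"zero total mass accumulated in {compartment!r}")
    return {form: m / total for form, m in means.items()}
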