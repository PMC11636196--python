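"""Material-flow engine: propagation, conservation, schedules, sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from numpy.testing import assert_allclose, assert_array_equal

from gbmrisk import (Compartment, CompartmentGraph, GraphError,
                     ProductionSeries, ReleaseSchedule, Scenario,
                     TransferCoefficientPrior, mass_balance_report,
                     propagate_year, run_simulation,
                     sample_transfer_coefficients, sink_distribution_by_form)


def chain_scenario(inflow_per_year, n_years=1, schedules=None):
    graph = CompartmentGraph(
        [Compartment("A"), Compartment("B"), Compartment("sink", "sink")],
        [("A", "B"), ("B", "sink")])
    priors = [TransferCoefficientPrior(("A", "B"), "point", (1.0,)),
              TransferCoefficientPrior(("B", "sink"), "point", (1.0,))]
    years = tuple(range(2020, 2020 + n_years))
    series = ProductionSeries(years, np.full((n_years, 1), inflow_per_year))
    return Scenario(graph, priors, {"A": series}, schedules or {})


class TestGraphValidation:
    def test_sink_with_outgoing_edge_rejected(self):
        with pytest.raises(GraphError, match="outgoing"):
            CompartmentGraph([Compartment("s", "sink"), Compartment("a")],
                             [("s", "a")])

    def test_transfer_without_outgoing_edge_rejected(self):
        with pytest.raises(GraphError, match="transfer"):
            CompartmentGraph([Compartment("air", "transfer")], [])

    def test_cycle_among_non_sinks_rejected(self):
        with pytest.raises(GraphError, match="cycle"):
            CompartmentGraph([Compartment("a"), Compartment("b")],
                             [("a", "b"), ("b", "a")])


class TestSampleTransferCoefficients:
    def test_single_edge_is_always_one(self):
        priors = [TransferCoefficientPrior(("a", "b"), "uniform", (0.1, 0.9))]
        tc = sample_transfer_coefficients(priors, seed=0, n_runs=50)
        assert_array_equal(tc["a"]["b"], np.ones(50))

    def test_point_priors_already_normalized_pass_through(self):
        priors = [TransferCoefficientPrior(("a", t), "point", (v,))
                  for t, v in [("x", 0.2), ("y", 0.3), ("z", 0.5)]]
        tc = sample_transfer_coefficients(priors, seed=1, n_runs=3)
        assert_allclose([tc["a"]["x"], tc["a"]["y"], tc["a"]["z"]],
                        [[0.2] * 3, [0.3] * 3, [0.5] * 3])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_renormalization_sums_to_one(self, seed):
        priors = [TransferCoefficientPrior(("a", "x"), "uniform", (0.4, 0.6)),
                  TransferCoefficientPrior(("a", "y"), "uniform", (0.4, 0.6))]
        tc = sample_transfer_coefficients(priors, seed=seed, n_runs=20)
        assert_allclose(tc["a"]["x"] + tc["a"]["y"], 1.0, atol=1e-12)

    def test_all_zero_draws_error(self):
        priors = [TransferCoefficientPrior(("a", "x"), "point", (0.0,)),
                  TransferCoefficientPrior(("a", "y"), "point", (0.0,))]
        with pytest.raises(GraphError, match="zero"):
            sample_transfer_coefficients(priors, seed=0, n_runs=2)


class TestPropagateYear:
    def test_chain_delivers_everything_to_sink(self):
        sc = chain_scenario(10.0)
        ens = run_simulation(sc, 1, seed=0)
        assert_allclose(ens.sinks["sink"], [10.0])
        assert_allclose(ens.stocks, 0.0)

    def test_two_branch_split(self):
        graph = CompartmentGraph(
            [Compartment("a"), Compartment("s1", "sink"), Compartment("s2", "sink")],
            [("a", "s1"), ("a", "s2")])
        coeffs = {"a": {"s1": np.array([0.7]), "s2": np.array([0.3])}}
        flows, _ = propagate_year(graph, coeffs, {"a": np.array([10.0])}, {}, {})
        assert_allclose(flows[("a", "s1")], [7.0])
        assert_allclose(flows[("a", "s2")], [3.0])

    def test_schedule_releases_fraction_of_stock(self):
        graph = CompartmentGraph(
            [Compartment("use"), Compartment("sink", "sink")],
            [("use", "sink")])
        coeffs = {"use": {"sink": np.array([1.0])}}
        sched = {"use": ReleaseSchedule("use", (0.0, 0.1))}
        stocks = {"use": {0: np.array([100.0])}}
        flows, stocks = propagate_year(graph, coeffs, {}, stocks, sched,
                                       year_index=1)
        assert_allclose(flows[("use", "sink")], [10.0])
        assert_allclose(stocks["use"][0], [90.0])


class TestRunSimulation:
    def test_point_priors_make_runs_identical(self, toy_bundle):
        from gbmrisk import SyntheticScenarioSpec, make_scenario

        b = make_scenario(SyntheticScenarioSpec(
            n_runs=5, production_cv=0.0, tc_spread=0.0, seed=1))
        ens = run_simulation(b.scenario, 5, seed=9)
        assert np.ptp(ens.flows, axis=0).max() == 0.0

    def test_constant_inflow_accumulates_linearly(self):
        sc = chain_scenario(7.0, n_years=6)
        ens = run_simulation(sc, 1, seed=0)
        assert_allclose(ens.accumulated[0, :, ens.terminals.index("sink")],
                        7.0 * np.arange(1, 7))

    def test_geometric_release_stock_matches_closed_form(self):
        r, Y, inflow = 0.3, 5, 1.0
        sched = {"B": ReleaseSchedule("B", tuple(r * (1 - r) ** k
                                                 for k in range(Y)))}
        sc = chain_scenario(inflow, n_years=Y, schedules=sched)
        ens = run_simulation(sc, 1, seed=0)
        stock = ens.stocks[0, -1, ens.compartments.index("B")]
        expected = inflow * sum((1 - r) ** k for k in range(1, Y + 1))
        assert_allclose(stock, expected, rtol=1e-12)

    def test_seed_determinism_bit_identical(self, toy_bundle):
        e1 = run_simulation(toy_bundle.scenario, 300, seed=5)
        e2 = run_simulation(toy_bundle.scenario, 300, seed=5)
        assert_array_equal(e1.flows, e2.flows)
        assert_array_equal(e1.stocks, e2.stocks)

    def test_linearity_in_production(self, toy_bundle):
        sc = toy_bundle.scenario
        ens = run_simulation(sc, 300, seed=3)
        scaled = Scenario(sc.graph, sc.priors,
                          {c: ProductionSeries(s.years, 2.5 * s.samples)
                           for c, s in sc.inflows.items()}, sc.schedules)
        ens2 = run_simulation(scaled, 300, seed=3)
        assert_allclose(ens2.flows, 2.5 * ens.flows, rtol=1e-12)
        assert_allclose(ens2.stocks, 2.5 * ens.stocks, rtol=1e-12)

    def test_transfer_compartment_holds_no_stock(self, toy_bundle):
        ens = run_simulation(toy_bundle.scenario, 300, seed=11)
        air = ens.compartments.index("air")
        assert_array_equal(ens.stocks[:, :, air], 0.0)
        # mass does flow through air within the year
        assert ens.edge_flow("air", "natural_soil").sum() > 0


class TestMassBalance:
    def test_valid_simulation_conserves(self, toy_bundle):
        ens = run_simulation(toy_bundle.scenario, 300, seed=2)
        rep = mass_balance_report(ens)
        assert rep["relative_residual"].abs().max() <= 1e-9

    def test_corrupted_ensemble_is_flagged(self, toy_bundle):
        ens = run_simulation(toy_bundle.scenario, 300, seed=2)
        ens.accumulated[:, :, 0] *= 2.0
        rep = mass_balance_report(ens)
        assert rep["relative_residual"].abs().max() > 1e-6

    def test_zero_inflow_residual_exactly_zero(self):
        sc = chain_scenario(0.0, n_years=3)
        ens = run_simulation(sc, 1, seed=0)
        assert_array_equal(mass_balance_report(ens)["residual_t"], 0.0)


class TestBruteForceOracle:
    def brute_force(self, splits, inflows_by_year, n_years):
        """Independent hand propagation: dict arithmetic, one pass per year."""
        acc = {}
        order = ["a", "b", "c"]
        for y in range(n_years):
            arriving = {k: 0.0 for k in ("a", "b", "c", "s1", "s2")}
            arriving["a"] += inflows_by_year[y]
            for comp in order:
                for tgt, tc in splits.get(comp, {}).items():
                    arriving[tgt] += arriving[comp] * tc
            for s in ("s1", "s2"):
                acc[s] = acc.get(s, 0.0) + arriving[s]
        return acc

    def test_four_compartment_point_tc_graph_matches_hand_propagation(self):
        splits = {"a": {"b": 0.6, "c": 0.4}, "b": {"s1": 1.0},
                  "c": {"s1": 0.25, "s2": 0.75}}
        graph = CompartmentGraph(
            [Compartment("a"), Compartment("b"), Compartment("c"),
             Compartment("s1", "sink"), Compartment("s2", "sink")],
            [(s, t) for s, tg in splits.items() for t in tg])
        priors = [TransferCoefficientPrior((s, t), "point", (v,))
                  for s, tg in splits.items() for t, v in tg.items()]
        inflows = [5.0, 11.0, 2.0]
        series = ProductionSeries((2020, 2021, 2022),
                                  np.array(inflows)[:, None])
        ens = run_simulation(Scenario(graph, priors, {"a": series}), 1, seed=0)
        expected = self.brute_force(splits, inflows, 3)
        for s in ("s1", "s2"):
            assert_allclose(ens.sinks[s][0], expected[s], rtol=1e-12)


class TestSinkDistributionByForm:
    def two_form_ensembles(self, tc1, tc2):
        out = {}
        for form, tc in (("f1", tc1), ("f2", tc2)):
            graph = CompartmentGraph(
                [Compartment("a"), Compartment("S", "sink"),
                 Compartment("E", "elimination")],
                [("a", "S"), ("a", "E")])
            priors = [TransferCoefficientPrior(("a", "S"), "point", (tc,)),
                      TransferCoefficientPrior(("a", "E"), "point", (1 - tc,))]
            series = ProductionSeries((2020,), [[100.0]])
            out[form] = run_simulation(Scenario(graph, priors, {"a": series}),
                                       1, seed=0)
        return out

    def test_identical_ensembles_give_equal_shares(self):
        shares = sink_distribution_by_form(self.two_form_ensembles(0.5, 0.5), "S")
        assert_allclose([shares["f1"], shares["f2"]], [0.5, 0.5])

    def test_two_to_one_routing(self):
        shares = sink_distribution_by_form(self.two_form_ensembles(0.5, 0.25), "S")
        assert_allclose([shares["f1"], shares["f2"]], [2 / 3, 1 / 3])

    def test_zero_total_mass_errors(self):
        with pytest.raises(GraphError, match="zero"):
            sink_distribution_by_form(self.two_form_ensembles(0.0, 0.0), "S")
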