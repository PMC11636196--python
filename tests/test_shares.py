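"""Form disaggregation: share-matrix algebra and the shipped split table."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from numpy.testing import assert_allclose

from gbmrisk import (GBM_FORMS, MarketMatrices, ProductionSeries, ShareMatrix,
                     ShareMatrixError, allocate_form_production,
                     apply_split_rules, combine_market_matrices,
                     compose_form_shares, default_form_split_matrix,
                     reallocate_categories)
from gbmrisk.shares import format_split_percent


def share_matrix(rows, cols, values):
    return ShareMatrix(tuple(rows), tuple(cols), np.asarray(values, float))


def random_stochastic(rng, n_rows, n_cols, row_prefix="r", col_prefix="c"):
    vals = rng.dirichlet(np.ones(n_cols), size=n_rows)
    return share_matrix([f"{row_prefix}{i}" for i in range(n_rows)],
                        [f"{col_prefix}{j}" for j in range(n_cols)], vals)


class TestShareMatrix:
    def test_rejects_bad_row_sum_naming_the_row(self):
        with pytest.raises(ShareMatrixError, match="2029") as err:
            share_matrix([2029], ["a", "b"], [[0.5, 0.3]])
        assert err.value.rows == [2029]

    def test_rejects_entries_outside_unit_interval(self):
        with pytest.raises(ShareMatrixError):
            share_matrix(["y"], ["a", "b"], [[1.5, -0.5]])

    def test_csv_round_trip(self, tmp_path, rng):
        m = random_stochastic(rng, 4, 3)
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = ShareMatrix.from_csv(path)
        assert_allclose(back.values, m.values)
        assert back.col_labels == m.col_labels


class TestComposeFormShares:
    def test_single_category_identity(self):
        E = share_matrix([2030], ["cat"], [[1.0]])
        F = share_matrix(["cat"], GBM_FORMS, [[1 / 3, 1 / 3, 1 / 3]])
        G = compose_form_shares(E, F)
        assert_allclose(G.values, [[1 / 3, 1 / 3, 1 / 3]])

    def test_hand_multiplied_two_categories(self):
        E = share_matrix([2030], ["a", "b"], [[0.5, 0.5]])
        F = share_matrix(["a", "b"], GBM_FORMS, [[1, 0, 0], [0, 1, 0]])
        G = compose_form_shares(E, F)
        assert_allclose(G.values, [[0.5, 0.5, 0.0]])

    def test_label_mismatch_reports_labels(self):
        E = share_matrix([2030], ["a"], [[1.0]])
        F = share_matrix(["b"], GBM_FORMS, [[1, 0, 0]])
        with pytest.raises(ShareMatrixError, match="'b'"):
            compose_form_shares(E, F)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_composition_preserves_row_stochasticity(self, seed):
        rng = np.random.default_rng(seed)
        E = random_stochastic(rng, 5, 4, col_prefix="k")
        F = random_stochastic(rng, 4, 3, row_prefix="k")
        G = compose_form_shares(E, F)
        assert_allclose(G.values.sum(axis=1), 1.0, atol=1e-9)


class TestReallocateCategories:
    def test_single_source_category(self):
        E = share_matrix([2029, 2030], ["only"], [[1.0], [1.0]])
        F = share_matrix(["only"], ["pG"], [[1.0]])
        G = compose_form_shares(E, F)
        out = reallocate_categories(E, F, G, "pG")
        assert_allclose(out.values, [[1.0], [1.0]])

    def test_hand_arithmetic(self):
        # e = (0.6, 0.4), f_z = (0.5, 1.0) -> g = 0.7
        E = share_matrix([2030], ["a", "b"], [[0.6, 0.4]])
        F = share_matrix(["a", "b"], ["z", "w"], [[0.5, 0.5], [1.0, 0.0]])
        G = compose_form_shares(E, F)
        out = reallocate_categories(E, F, G, "z")
        assert_allclose(out.values, [[0.6 * 0.5 / 0.7, 0.4 * 1.0 / 0.7]])
        assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-9)

    def test_form_with_zero_share_raises_with_year(self):
        E = share_matrix([2030], ["a"], [[1.0]])
        F = share_matrix(["a"], ["z", "w"], [[0.0, 1.0]])
        G = compose_form_shares(E, F)
        with pytest.raises(ShareMatrixError, match="2030"):
            reallocate_categories(E, F, G, "z")


class TestAllocateFormProduction:
    def test_exact_split(self):
        G = share_matrix([2030], GBM_FORMS, [[0.5, 0.25, 0.25]])
        P = ProductionSeries((2030,), [[100.0]])
        out = [allocate_form_production(P, G, f).samples[0, 0] for f in GBM_FORMS]
        assert_allclose(out, [50, 25, 25])

    def test_zero_production(self):
        G = share_matrix([2030], GBM_FORMS, [[0.5, 0.25, 0.25]])
        P = ProductionSeries((2030,), [[0.0]])
        for f in GBM_FORMS:
            assert allocate_form_production(P, G, f).samples[0, 0] == 0

    def test_missing_year_raises(self):
        G = share_matrix([2029], GBM_FORMS, [[0.5, 0.25, 0.25]])
        P = ProductionSeries((2030,), [[1.0]])
        with pytest.raises(ShareMatrixError, match="2030"):
            allocate_form_production(P, G, "pG")

    @given(st.integers(0, 2 ** 31 - 1))
    def test_form_totals_conserve_production(self, seed):
        rng = np.random.default_rng(seed)
        years = tuple(range(2025, 2030))
        G = share_matrix(years, GBM_FORMS, rng.dirichlet(np.ones(3), 5))
        P = ProductionSeries(years, rng.gamma(2, 50, size=(5, 20)))
        total = sum(allocate_form_production(P, G, f).samples for f in GBM_FORMS)
        assert_allclose(total, P.samples, rtol=1e-9)


class TestCombineMarketMatrices:
    def test_single_form(self):
        M = MarketMatrices(("pG",), ("app1", "app2"), [1.0], [[0.5, 0.5]])
        D = combine_market_matrices(M)
        assert_allclose(D.values, [[1.0], [1.0]])

    def test_symmetric_two_forms(self):
        M = MarketMatrices(("pG", "GO"), ("app",), [0.5, 0.5], [[1.0], [1.0]])
        D = combine_market_matrices(M)
        assert_allclose(D.values, [[0.5, 0.5]])

    def test_hand_arithmetic_market_weights(self):
        # A = (0.62, 0.38) with per-form application weights 0.8 / 0.2
        M = MarketMatrices(("pG", "GO"), ("app", "rest"),
                           [0.62, 0.38], [[0.8, 0.2], [0.2, 0.8]])
        D = combine_market_matrices(M)
        assert_allclose(D.values[0], [0.62 * 0.8 / 0.572, 0.38 * 0.2 / 0.572],
                        rtol=1e-12)
        assert_allclose(D.values[0], [0.8671, 0.1329], atol=5e-5)

    def test_zero_weight_application_raises(self):
        M = MarketMatrices(("pG", "GO"), ("app", "dead"),
                           [0.5, 0.5], [[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ShareMatrixError, match="dead"):
            combine_market_matrices(M)


class TestSplitRules:
    @pytest.mark.parametrize("spec, expected", [
        ({"rule": "go_halving", "pg": 0.0, "go": 1.0}, (0.0, 0.5, 0.5)),
        ({"rule": "equal", "forms": list(GBM_FORMS)}, (1 / 3, 1 / 3, 1 / 3)),
        ({"rule": "explicit", "shares": [0.71, 0.17, 0.12]}, (0.71, 0.17, 0.12)),
    ])
    def test_rules(self, spec, expected):
        assert_allclose(apply_split_rules(spec), expected)

    def test_mixture_of_base_rows(self):
        base = {"composite": (1.0, 0.0, 0.0), "others": (0.0, 1.0, 0.0)}
        row = apply_split_rules(
            {"rule": "mixture", "components": [
                {"base": "composite", "weight": 0.9},
                {"base": "others", "weight": 0.1}]},
            base_rows=base)
        assert_allclose(row, (0.9, 0.1, 0.0))

    def test_unknown_rule_and_bad_weights(self):
        with pytest.raises(ShareMatrixError, match="unknown split rule"):
            apply_split_rules({"rule": "nope"})
        with pytest.raises(ShareMatrixError, match="weights"):
            apply_split_rules({"rule": "mixture", "components": [
                {"base": "x", "weight": 0.5}]}, base_rows={"x": (1, 0, 0)})

    @given(arrays(float, 3, elements=st.floats(0.01, 1.0)))
    def test_equal_split_always_sums_to_one(self, _ignored):
        row = apply_split_rules({"rule": "equal", "forms": ["pG", "GO"]})
        assert abs(row.sum() - 1) < 1e-9


class TestDefaultSplitTable:
    def test_shipped_table_is_row_stochastic_with_14_categories(self):
        F = default_form_split_matrix()
        assert F.shape == (14, 3)
        assert_allclose(F.values.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("category, printed", [
        ("construction", (0, 50, 50)),
        ("drilling_fluid", (33, 33, 33)),
        ("aerospace_aviation", (81, 10, 10)),
        ("automotive", (77, 12, 12)),
        ("batteries", (57, 22, 22)),
        ("electronics", (100, 0, 0)),
        ("research_development", (71, 17, 12)),
    ])
    def test_printed_rounding_of_shipped_rows(self, category, printed):
        F = default_form_split_matrix()
        assert format_split_percent(F.row(category)) == printed
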