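"""Cyclodextrin-conjugate family: partitions, closed forms, verification."""

from fractions import Fraction

import pytest

from mpolytop.family import (
    builtin_model,
    closed_form,
    model_at,
    realize_graph,
    round_half_even,
    symbolic_mpoly,
    verify_printed_theorems,
)
from mpolytop.graphs import edge_partition
from mpolytop.indices import ALL_INDEX_NAMES, DEFAULT_ALPHAS, index_from_partition


class TestBuiltinModels:
    def test_degree_base_counts(self):
        part = model_at(builtin_model("degree"), 0)
        assert part.classes == {(1, 2): 15, (2, 4): 35, (1, 4): 35, (4, 4): 25}

    def test_degree_counts_at_n1(self):
        part = model_at(builtin_model("degree"), 1)
        assert part.classes == {(1, 2): 18, (2, 4): 42, (1, 4): 42, (4, 4): 30}

    def test_neighborhood_base_counts(self):
        part = model_at(builtin_model("neighborhood"), 0)
        assert part.classes == {
            (2, 5): 15, (4, 8): 10, (4, 9): 5, (4, 11): 20, (5, 8): 5,
            (5, 11): 10, (8, 9): 10, (8, 11): 15, (9, 11): 5, (11, 11): 15,
        }

    def test_totals_linear_in_n(self):
        for basis in ("degree", "neighborhood"):
            assert builtin_model(basis).edge_total() == (22, 110)
        assert builtin_model("degree").vertex_total() == (21, 105)

    def test_vertex_counts_at_base(self):
        vc = builtin_model("degree").vertex_counts
        assert {deg: i for deg, (_, i) in vc.items()} == {1: 50, 2: 25, 4: 30}

    def test_handshake_across_n(self):
        model = builtin_model("degree")
        for n in range(11):
            stubs = sum(
                deg * (s * n + i) for deg, (s, i) in model.vertex_counts.items()
            )
            assert stubs == 2 * (22 * n + 110)

    def test_intercept_is_five_slopes_per_class(self):
        for basis in ("degree", "neighborhood"):
            for slope, intercept in builtin_model(basis).classes.values():
                assert intercept == 5 * slope

    @pytest.mark.parametrize("bad_n", [-1, 1.5, "2"])
    def test_model_at_rejects_bad_n(self, bad_n):
        with pytest.raises((ValueError, TypeError)):
            model_at(builtin_model("degree"), bad_n)


class TestSymbolicRendering:
    def test_degree_polynomial_text(self):
        text = symbolic_mpoly(builtin_model("degree"))
        assert text == (
            "(3n+15)c^1d^2 + (7n+35)c^1d^4 + (7n+35)c^2d^4 + (5n+25)c^4d^4"
        )

    def test_neighborhood_contains_printed_term(self):
        assert "(4n+20)c^4d^11" in symbolic_mpoly(builtin_model("neighborhood"))


class TestClosedForms:
    @pytest.mark.parametrize(
        "name, slope, intercept",
        [
            ("M1", 126, 630),
            ("M2", 170, 850),
            ("F", 434, 2170),
            ("ReZG3", 1134, 5670),
            ("SDD", Fraction(259, 4), Fraction(1295, 4)),
            ("ISI", Fraction(404, 15), Fraction(404, 3)),
            ("AZI", Fraction(5168, 27), Fraction(25840, 27)),
            ("mM2", Fraction(71, 16), Fraction(355, 16)),
            ("H", Fraction(503, 60), Fraction(503, 12)),
        ],
    )
    def test_degree_model_forms(self, name, slope, intercept):
        form = closed_form(name, builtin_model("degree"))
        assert (form.slope, form.intercept) == (slope, intercept)

    @pytest.mark.parametrize(
        "name, slope, intercept",
        [
            ("nM1", 340, 1700),
            ("nM2", 1326, 6630),
            ("nF", 3046, 15230),
            ("nReZG3", 23796, 118980),
            ("nSDD", Fraction(108421, 1980), Fraction(108421, 396)),
            ("nmM2", Fraction(55697, 87120), Fraction(55697, 17424)),
        ],
    )
    def test_neighborhood_model_forms(self, name, slope, intercept):
        form = closed_form(name, builtin_model("neighborhood"))
        assert (form.slope, form.intercept) == (slope, intercept)

    def test_gr_at_plus_minus_one(self):
        model = builtin_model("degree")
        assert closed_form("GR", model, Fraction(1)).slope == 170
        assert closed_form("GR", model, Fraction(-1)).slope == Fraction(71, 16)

    def test_intercept_is_five_times_slope_for_every_index(self):
        for basis in ("degree", "neighborhood"):
            model = builtin_model(basis)
            prefix = "n" if basis == "neighborhood" else ""
            for name in ALL_INDEX_NAMES:
                if not name.startswith(prefix) or (prefix == "" and name.startswith("n")):
                    continue
                alphas = DEFAULT_ALPHAS if name.endswith("GR") else (None,)
                for alpha in alphas:
                    form = closed_form(name, model, alpha)
                    assert form.intercept == 5 * form.slope, (name, alpha)

    @pytest.mark.parametrize("n", [0, 2, 7])
    def test_form_reproduces_pointwise_values(self, n):
        model = builtin_model("degree")
        for name in ("M1", "AZI", "SDD", "H"):
            form = closed_form(name, model)
            assert form.at(n) == index_from_partition(name, model_at(model, n))


class TestVerificationReport:
    def test_statuses(self):
        statuses = {e.name: e.status for e in verify_printed_theorems()}
        assert statuses["M1"] == "match"
        assert statuses["F"] == "match"
        assert statuses["ReZG3"] == "match"
        assert statuses["SDD"] == "match"
        assert statuses["ISI"] == "match"
        assert statuses["AZI"] == "match"
        assert statuses["GR@1"] == "match"
        assert statuses["GR@-1"] == "match"
        for name in ("nM1", "nM2", "nF", "nReZG3", "nSDD", "nAZI"):
            assert statuses[name] == "match", name
        # printed coefficients inconsistent with the printed partitions
        for name in ("M2", "mM2", "H", "nH", "nISI", "nmM2"):
            assert statuses[name] == "mismatch", name

    def test_mismatches_report_both_values(self):
        entries = {e.name: e for e in verify_printed_theorems()}
        mm2 = entries["mM2"]
        assert mm2.computed.slope == Fraction(71, 16)
        assert mm2.printed_slope.value == Fraction(61, 16)
        assert not mm2.slope_matches and mm2.intercept_matches
        h = entries["H"]
        assert h.slope_matches and not h.intercept_matches
        m2 = entries["M2"]
        assert m2.slope_matches and not m2.intercept_matches
        assert m2.computed.intercept == 850 and m2.printed_intercept.value == 830


class TestRounding:
    def test_round_half_even(self):
        assert round_half_even(Fraction(5, 2), 0) == 2.0
        assert round_half_even(Fraction(108421, 1980), 3) == 54.758


class TestRealization:
    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_realized_graph_matches_model(self, n):
        model = builtin_model("degree")
        g = realize_graph(model, n)
        assert g.n_vertices == 21 * n + 105
        assert g.n_edges == 22 * n + 110
        assert edge_partition(g, "degree").classes == model_at(model, n).classes

    def test_neighborhood_partition_reported_but_differs(self):
        # the realization matches the degree model; its neighborhood classes
        # need not (and do not) reproduce the published neighborhood model
        g = realize_graph(builtin_model("degree"), 0)
        nbhd = edge_partition(g, "neighborhood")
        assert nbhd.total_edges == 110
        assert nbhd.classes != model_at(builtin_model("neighborhood"), 0).classes
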