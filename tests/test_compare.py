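import math

import pytest
from hypothesis import given, settings, strategies as st

from kinnet import (
    Metabolite,
    ScanItem,
    compare_models,
    derive_node_styles,
    intersect_elements,
    percentage_change,
    perturbation_compare,
)
from kinnet.compare import PC_INFINITE, ComparisonResult
from kinnet.errors import ComparisonError

from .conftest import decay_model, influx_decay_model


class TestPercentageChange:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (10.0, 10.0, 0.0),
            (2.0, 5.0, 150.0),
            (0.0, 0.0, 0.0),
            (4.0, 1.0, -75.0),
            (1.0, 0.0, -100.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert percentage_change(a, b) == pytest.approx(expected)

    def test_zero_reference_is_infinite(self):
        assert math.isinf(percentage_change(0.0, 3.0))
        assert percentage_change(0.0, 3.0) > 0

    def test_negative_input_rejected(self):
        with pytest.raises(ComparisonError):
            percentage_change(-1.0, 2.0)
        with pytest.raises(ComparisonError):
            percentage_change(1.0, -2.0)

    @given(st.floats(0.01, 1e6), st.floats(1e-3, 1e3))
    @settings(derandomize=True, max_examples=100)
    def test_sign_flip_metamorphic(self, a, ratio):
        b = a * ratio
        """Swapping reference and perturbed flips the sign, with
        magnitudes related by PC' = -100*PC/(100+PC)."""
        pc = percentage_change(a, b)
        pc_swapped = percentage_change(b, a)
        assert (pc > 0) == (pc_swapped < 0) or pc == pc_swapped == 0
        assert pc_swapped == pytest.approx(-100.0 * pc / (100.0 + pc), rel=1e-9)


class TestIntersection:
    def test_identity(self):
        m = decay_model()
        pairs, un_ref, un_pert = intersect_elements(m, m.copy())
        assert pairs == [("A", "A"), ("B", "B")]
        assert un_ref == un_pert == []

    def test_added_drug_reported_unmatched(self):
        ref = decay_model()
        pert = decay_model()
        pert.add_metabolite(Metabolite(id="drug", initial_concentration=0.0))
        pairs, un_ref, un_pert = intersect_elements(ref, pert)
        assert [p[0] for p in pairs] == ["A", "B"]
        assert un_pert == ["drug"]

    def test_name_fallback_matching(self):
        ref = decay_model()
        pert = decay_model()
        pert.metabolite("A").id = "A_renamed"
        pert.reaction("r1").reactants = {"A_renamed": 1}
        pairs, un_ref, _ = intersect_elements(ref, pert)
        assert ("A", "A_renamed") in pairs
        assert un_ref == []

    def test_disjoint_models_error(self):
        ref = decay_model()
        pert = influx_decay_model()
        pert.metabolite("A").id = "Z"
        pert.metabolite("Z").name = "Z"
        for r in pert.reactions:
            r.reactants = {("Z" if s == "A" else s): c for s, c in r.reactants.items()}
            r.products = {("Z" if s == "A" else s): c for s, c in r.products.items()}
        with pytest.raises(ComparisonError):
            intersect_elements(ref, pert)


class TestCompareModels:
    def test_self_comparison_all_zero(self, decay):
        cr = compare_models(decay, decay.copy(), "timecourse_final", 5.0, 50)
        assert all(pc == 0.0 for pc in cr.pc)
        styles = derive_node_styles(cr)
        assert all(not s.visible for s in styles)

    def test_steadystate_mode(self):
        ref = influx_decay_model(v=2.0, k=0.5)  # [A]ss = 4
        pert = influx_decay_model(v=2.0, k=1.0)  # [A]ss = 2
        cr = compare_models(ref, pert, "steadystate")
        assert cr.pc_of("A") == pytest.approx(-50.0, rel=1e-5)

    def test_timecourse_final_uses_common_duration(self, decay):
        pert = decay_model(k=0.2)
        cr = compare_models(decay, pert, "timecourse_final", 10.0, 100)
        a_ref, a_pert = math.exp(-1.0), math.exp(-2.0)
        assert cr.comparison_time == 10.0
        assert cr.pc_of("A") == pytest.approx(100 * (a_pert - a_ref) / a_ref, rel=1e-4)

    def test_no_steady_state_is_comparison_error(self):
        from kinnet.model import Model, Reaction
        from kinnet.ratelaws import custom_rate_law

        div = Model(id="div")
        div.add_metabolite(Metabolite(id="A"))
        div.add_reaction(
            Reaction(
                id="in", reactants={}, products={"A": 1},
                rate_law=custom_rate_law("c", "v", ["v"]),
                parameter_values={"v": 1.0},
            )
        )
        with pytest.raises(ComparisonError):
            compare_models(div, div.copy(), "steadystate")


class TestPerturbationCompare:
    def test_empty_items_all_zero(self, decay):
        cr = perturbation_compare(decay, [], "timecourse_final", 5.0, 20)
        assert all(pc == 0.0 for pc in cr.pc)

    def test_matches_two_model_comparison(self, decay):
        items = [ScanItem("reaction.r1.k", 0.1, 0.2)]
        cr_scan = perturbation_compare(decay, items, "timecourse_final", 10.0, 100)
        pert_model = decay_model(k=0.2)
        cr_models = compare_models(decay, pert_model, "timecourse_final", 10.0, 100)
        assert cr_scan.pc_of("A") == pytest.approx(cr_models.pc_of("A"), rel=1e-6)

    def test_model_untouched(self, decay):
        before = decay.to_json()
        perturbation_compare(
            decay, [ScanItem("reaction.r1.k", 0.1, 0.9)], "timecourse_final", 2.0, 10
        )
        assert decay.to_json() == before


def _cr(ids, a, b):
    return ComparisonResult(
        metabolite_ids=ids,
        reference_values=a,
        perturbed_values=b,
        pc=[percentage_change(x, y) for x, y in zip(a, b)],
        mode="timecourse_final",
        comparison_time=1.0,
    )


class TestNodeStyles:
    def test_zero_pc_invisible(self):
        styles = derive_node_styles(_cr(["m"], [5.0], [5.0]))
        assert styles[0].visible is False
        assert styles[0].color == "neutral"

    def test_up_red_down_cyan(self):
        styles = derive_node_styles(_cr(["up", "down"], [1.0, 2.0], [3.0, 1.0]))
        by_id = {s.metabolite_id: s for s in styles}
        assert by_id["up"].color == "red"
        assert by_id["down"].color == "cyan"

    def test_largest_change_gets_max_size(self):
        styles = derive_node_styles(
            _cr(["small", "huge"], [1.0, 1e-4], [1.1, 100.0]),
            size_min=10, size_max=90,
        )
        by_id = {s.metabolite_id: s for s in styles}
        assert by_id["huge"].size == pytest.approx(90.0)
        assert by_id["small"].size < by_id["huge"].size

    def test_infinite_sentinel_max_size_red(self):
        styles = derive_node_styles(
            _cr(["new", "ref"], [0.0, 1.0], [5.0, 2.0]), size_min=10, size_max=90
        )
        by_id = {s.metabolite_id: s for s in styles}
        assert math.isinf(by_id["new"].tooltip[0])
        assert by_id["new"].size == 90.0
        assert by_id["new"].color == "red"
        assert by_id["new"].visible

    def test_size_monotone_in_abs_pc(self):
        a = [1.0] * 5
        b = [1.0, 1.5, 3.0, 10.0, 1000.0]
        styles = derive_node_styles(_cr(list("vwxyz"), a, b))
        sizes = [s.size for s in styles]
        assert sizes == sorted(sizes)

    def test_tooltip_carries_values(self):
        styles = derive_node_styles(_cr(["m"], [2.0], [5.0]))
        assert styles[0].tooltip == (150.0, 2.0, 5.0)

    def test_exports(self, tmp_path, decay):
        cr = compare_models(decay, decay_model(k=0.2), "timecourse_final", 5.0, 20)
        tsv = tmp_path / "cr.tsv"
        cr.to_tsv(tsv)
        assert tsv.read_text().splitlines()[0].split("\t") == [
            "metabolite", "reference", "perturbed", "pc",
        ]
        import json

        doc = json.loads(cr.to_json(styles=derive_node_styles(cr)))
        assert {m["id"] for m in doc["metabolites"]} == {"A", "B"}
        assert "styles" in doc
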