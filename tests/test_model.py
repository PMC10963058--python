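import math

import pytest
from hypothesis import given, settings, strategies as st

from kinnet import (
    BUILTIN_LIBRARY,
    Metabolite,
    Model,
    Reaction,
    builtin_rate_law,
    custom_rate_law,
    evaluate_rate,
    parse_reaction_equation,
    suggest_rate_laws,
)
from kinnet._expr import ExpressionError
from kinnet.errors import (
    ConflictError,
    EquationParseError,
    EvaluationError,
    IntegrityError,
)

from .conftest import decay_model


class TestEquationGrammar:
    @pytest.mark.parametrize(
        "text,reactants,products,reversible",
        [
            ("A -> B", {"A": 1}, {"B": 1}, False),
            ("2 A + B <-> C", {"A": 2, "B": 1}, {"C": 1}, True),
            ("A = B", {"A": 1}, {"B": 1}, True),
            ("  A +  B ->  2 C ", {"A": 1, "B": 1}, {"C": 2}, False),
            ("-> A", {}, {"A": 1}, False),  # pure source
            ("A ->", {"A": 1}, {}, False),  # pure sink
            ("A + A -> B", {"A": 2}, {"B": 1}, False),  # repeated species sum
        ],
    )
    def test_parses(self, text, reactants, products, reversible):
        assert parse_reaction_equation(text) == (reactants, products, reversible)

    @pytest.mark.parametrize(
        "text",
        ["A + -> B", "A B C", "A -> + B", "0 A -> B", "1.5 A -> B", "->"],
    )
    def test_malformed(self, text):
        with pytest.raises(EquationParseError):
            parse_reaction_equation(text)

    @given(
        st.lists(
            st.tuples(st.sampled_from("WXYZ"), st.integers(1, 5)),
            min_size=1, max_size=3, unique_by=lambda t: t[0],
        ),
        st.lists(
            st.tuples(st.sampled_from("PQRS"), st.integers(1, 5)),
            min_size=1, max_size=3, unique_by=lambda t: t[0],
        ),
        st.booleans(),
    )
    @settings(derandomize=True, max_examples=50)
    def test_format_parse_roundtrip(self, lhs, rhs, reversible):
        arrow = "<->" if reversible else "->"
        text = (
            " + ".join(f"{c} {s}" for s, c in lhs)
            + f" {arrow} "
            + " + ".join(f"{c} {s}" for s, c in rhs)
        )
        assert parse_reaction_equation(text) == (dict(lhs), dict(rhs), reversible)


class TestRateLawSuggestion:
    def _reaction(self, reactants, products, reversible=False):
        return Reaction(
            id="r", reactants=reactants, products=products, reversible=reversible
        )

    def test_irreversible_1_1(self):
        laws = suggest_rate_laws(self._reaction({"A": 1}, {"B": 1}))
        names = [law.name for law in laws]
        assert names[0] == "Irreversible mass action"
        assert "Irreversible Michaelis-Menten" in names
        assert all(not law.reversible_compatible for law in laws)

    def test_reversible_1_1(self):
        laws = suggest_rate_laws(self._reaction({"A": 1}, {"B": 1}, reversible=True))
        names = [law.name for law in laws]
        assert "Reversible mass action" in names
        assert "Irreversible mass action" not in names
        assert names[0] == "Reversible mass action"  # mass action first

    def test_bimolecular_vs_unimolecular_library(self):
        unimolecular_only = [
            law for law in BUILTIN_LIBRARY if law.arity == (1, 1)
        ]
        laws = suggest_rate_laws(
            self._reaction({"A": 1, "B": 1}, {"C": 1}), unimolecular_only
        )
        assert laws == []

    def test_stoichiometric_multiplicity_counts(self):
        # 2A -> B has two reactant molecules: unimolecular MM must not match
        laws = suggest_rate_laws(self._reaction({"A": 2}, {"B": 1}))
        assert all(law.is_mass_action for law in laws)

    def test_subset_and_deterministic(self):
        r = self._reaction({"A": 1}, {"B": 1})
        first = suggest_rate_laws(r, BUILTIN_LIBRARY)
        assert suggest_rate_laws(r, BUILTIN_LIBRARY) == first
        assert set(first) <= set(BUILTIN_LIBRARY)


class TestEvaluateRate:
    def test_mass_action_zero_substrate(self):
        law = builtin_rate_law("Irreversible mass action")
        assert evaluate_rate(law, {"A": 0.0}, {"k": 0.5}, reactants={"A": 1}) == 0.0

    def test_michaelis_menten_half_saturation(self):
        law = builtin_rate_law("Irreversible Michaelis-Menten")
        v = evaluate_rate(law, {"S": 2.0}, {"V": 10.0, "Km": 2.0},
                          reactants={"S": 1}, products={"P": 1})
        assert v == pytest.approx(5.0)

    def test_reversible_mass_action_equilibrium(self):
        law = builtin_rate_law("Reversible mass action")
        v = evaluate_rate(law, {"A": 1.0, "B": 2.0}, {"kf": 2.0, "kr": 1.0},
                          reactants={"A": 1}, products={"B": 1})
        assert v == pytest.approx(0.0)

    def test_competitive_inhibition_reduces_rate(self):
        law = builtin_rate_law("Competitive inhibition Michaelis-Menten")
        kwargs = dict(reactants={"S": 1}, products={"P": 1}, inhibitor="I")
        params = {"V": 10.0, "Km": 2.0, "Ki": 1.0}
        uninhibited = evaluate_rate(law, {"S": 2.0, "I": 0.0}, params, **kwargs)
        inhibited = evaluate_rate(law, {"S": 2.0, "I": 5.0}, params, **kwargs)
        assert uninhibited == pytest.approx(5.0)
        assert inhibited < uninhibited
        # closed form V*S/(Km*(1+I/Ki)+S)
        assert inhibited == pytest.approx(10.0 * 2.0 / (2.0 * 6.0 + 2.0))

    def test_unbound_symbol(self):
        law = custom_rate_law("bad", "k * missing", ["k"])
        with pytest.raises(EvaluationError):
            evaluate_rate(law, {"A": 1.0}, {"k": 1.0})

    def test_negative_concentration_rejected(self):
        law = builtin_rate_law("Irreversible mass action")
        with pytest.raises(EvaluationError):
            evaluate_rate(law, {"A": -1.0}, {"k": 1.0}, reactants={"A": 1})

    def test_singularity(self):
        law = builtin_rate_law("Irreversible Michaelis-Menten")
        with pytest.raises(EvaluationError):
            evaluate_rate(law, {"S": 0.0}, {"V": 10.0, "Km": 0.0},
                          reactants={"S": 1}, products={"P": 1})

    @given(st.floats(0.0, 100.0), st.floats(0.01, 10.0))
    @settings(derandomize=True, max_examples=50)
    def test_mass_action_continuous_and_nonnegative(self, conc, k):
        law = builtin_rate_law("Irreversible mass action")
        v = evaluate_rate(law, {"A": conc}, {"k": k}, reactants={"A": 2})
        assert v == pytest.approx(k * conc**2)
        assert v >= 0


class TestExpressionSecurity:
    @pytest.mark.parametrize(
        "source",
        [
            "__import__('os').system('true')",
            "(lambda: 1)()",
            "[1 for _ in range(2)]",
            "k.__class__",
            "open('/etc/passwd')",
        ],
    )
    def test_general_code_rejected(self, source):
        with pytest.raises(ExpressionError):
            custom_rate_law("evil", source, ["k"])

    def test_allowed_functions(self):
        law = custom_rate_law("fine", "pow(S, 2) + exp(0) + log(1) - sqrt(4)", [])
        assert evaluate_rate(law, {"S": 3.0}, {}) == pytest.approx(9.0 + 1.0 + 0.0 - 2.0)


class TestModelEditing:
    def test_remove_reaction_keeps_metabolites(self):
        m = decay_model()
        m.remove_reaction("r1")
        assert m.reaction_ids == []
        assert m.metabolite_ids == ["A", "B"]

    def test_remove_referenced_metabolite_rejected(self):
        m = decay_model()
        with pytest.raises(IntegrityError):
            m.remove_metabolite("A")

    def test_duplicate_id_conflict(self):
        m = decay_model()
        with pytest.raises(ConflictError):
            m.add_metabolite(Metabolite(id="A"))
        with pytest.raises(ConflictError):
            m.add_metabolite(Metabolite(id="r1"))  # namespaces disjoint

    def test_add_then_remove_is_identity(self):
        m = decay_model()
        snapshot = m.to_dict()
        m.add_metabolite(Metabolite(id="X", initial_concentration=1.0))
        m.add_reaction(
            Reaction(
                id="rX",
                reactants={"X": 1},
                products={"B": 1},
                rate_law=builtin_rate_law("Irreversible mass action"),
                parameter_values={"k": 1.0},
            )
        )
        m.remove_reaction("rX")
        m.remove_metabolite("X")
        assert m.to_dict() == snapshot

    def test_add_drug_bookkeeping(self):
        # adding a drug metabolite plus its inhibition reaction grows the
        # model by exactly one metabolite and one reaction
        m = decay_model()
        n_m, n_r = len(m.metabolites), len(m.reactions)
        m.add_metabolite(Metabolite(id="drug", initial_concentration=0.0))
        m.add_reaction(
            Reaction(
                id="r_drug",
                reactants={"B": 1},
                products={"A": 1},
                modifiers=[("drug", "catalyst")],
                rate_law=custom_rate_law("drug action", "k * drug * B", ["k"]),
                parameter_values={"k": 1e-3},
            )
        )
        m.validate()
        assert len(m.metabolites) == n_m + 1
        assert len(m.reactions) == n_r + 1

    def test_parameter_values_must_cover_slots(self):
        m = decay_model()
        m.reaction("r1").parameter_values = {"k": 0.1, "extra": 1.0}
        with pytest.raises(IntegrityError):
            m.validate()

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(IntegrityError):
            Metabolite(id="A", initial_concentration=-1.0)

    def test_fractional_stoichiometry_rejected(self):
        with pytest.raises(EquationParseError):
            Reaction(id="r", reactants={"A": 1.5}, products={"B": 1})


class TestSerialization:
    def test_json_roundtrip(self):
        m = decay_model()
        m.global_parameters["V1"] = 100.0
        restored = Model.from_json(m.to_json())
        assert restored.structurally_equal(m)

    def test_json_roundtrip_custom_law(self, tmp_path):
        m = decay_model()
        m.add_reaction(
            Reaction(
                id="r2",
                reactants={"B": 1},
                products={"A": 1},
                rate_law=custom_rate_law("back", "kb * B", ["kb"]),
                parameter_values={"kb": 0.5},
            )
        )
        path = tmp_path / "m.json"
        m.to_json(path)
        restored = Model.from_json(path)
        assert restored.structurally_equal(m)
        assert not math.isnan(restored.reaction("r2").parameter_values["kb"])
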