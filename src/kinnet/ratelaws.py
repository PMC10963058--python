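"""Rate-law library: built-in kinetic functions and user-defined expressions.

A :class:`RateLaw` is a named kinetic function with an ordered list of
parameter slots and an arity constraint (how many reactant/product
molecules, counted with stoichiometric multiplicity, it applies to).
Built-in laws are structural: their concrete formula is generated for a
given reaction (mass action multiplies the actual reactants).  Custom
laws carry an explicit arithmetic expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ._expr import Expression, ExpressionError
from .errors import EvaluationError

#: wildcard arity — matches any count
ANY = -1

MASS_ACTION_IRREVERSIBLE = "mass_action_irreversible"
MASS_ACTION_REVERSIBLE = "mass_action_reversible"
MICHAELIS_MENTEN_IRREVERSIBLE = "michaelis_menten_irreversible"
MICHAELIS_MENTEN_REVERSIBLE = "michaelis_menten_reversible"
MICHAELIS_MENTEN_COMPETITIVE = "michaelis_menten_competitive_inhibition"


@dataclass(frozen=True)
class RateLaw:
    """A named kinetic function with parameter slots and arity constraints.

    ``kind`` selects a built-in structural form, or ``"custom"`` in which
    case ``expression`` holds the formula over species and parameter
    symbols.
    """

    name: str
    parameter_slots: tuple[str, ...]
    arity: tuple[int, int] = (ANY, ANY)
    reversible_compatible: bool = False
    kind: str = "custom"
    expression: Optional[str] = None
    _compiled: Optional[Expression] = field(
        default=None, repr=False, compare=False, hash=False
    )

    def __post_init__(self):
        if self.kind == "custom":
            if not self.expression:
                raise ValueError("custom rate law requires an expression")
            object.__setattr__(self, "_compiled", Expression(self.expression))

    @property
    def is_mass_action(self) -> bool:
        return self.kind in (MASS_ACTION_IRREVERSIBLE, MASS_ACTION_REVERSIBLE)

    def matches(self, n_reactants: int, n_products: int, reversible: bool) -> bool:
        nr, np_ = self.arity
        return (
            (nr == ANY or nr == n_reactants)
            and (np_ == ANY or np_ == n_products)
            and self.reversible_compatible == reversible
        )

    # -- formula construction -------------------------------------------------

    def build_expression(
        self,
        reactants: Mapping[str, int],
        products: Mapping[str, int],
        inhibitor: Optional[str] = None,
    ) -> str:
        """Concrete formula of this law for a specific reaction."""
        if self.kind == "custom":
            return self.expression  # type: ignore[return-value]

        def monomial(stoich: Mapping[str, int]) -> str:
            terms = []
            for sid, coef in stoich.items():
                terms.append(sid if coef == 1 else f"{sid}^{coef}")
            return " * ".join(terms) if terms else "1"

        if self.kind == MASS_ACTION_IRREVERSIBLE:
            return f"k * {monomial(reactants)}"
        if self.kind == MASS_ACTION_REVERSIBLE:
            return f"kf * {monomial(reactants)} - kr * {monomial(products)}"

        if len(reactants) != 1:
            raise EvaluationError(
                f"{self.name} requires exactly one substrate, got {len(reactants)}"
            )
        S = next(iter(reactants))
        if self.kind == MICHAELIS_MENTEN_IRREVERSIBLE:
            return f"V * {S} / (Km + {S})"
        if self.kind == MICHAELIS_MENTEN_REVERSIBLE:
            if len(products) != 1:
                raise EvaluationError(
                    f"{self.name} requires exactly one product, got {len(products)}"
                )
            P = next(iter(products))
            return (
                f"(Vf * {S} / Kms - Vr * {P} / Kmp)"
                f" / (1 + {S} / Kms + {P} / Kmp)"
            )
        if self.kind == MICHAELIS_MENTEN_COMPETITIVE:
            if inhibitor is None:
                raise EvaluationError(
                    f"{self.name} requires an inhibitor modifier on the reaction"
                )
            return f"V * {S} / (Km * (1 + {inhibitor} / Ki) + {S})"
        raise EvaluationError(f"unknown rate-law kind {self.kind!r}")


# -- the built-in library -----------------------------------------------------

IRREVERSIBLE_MASS_ACTION = RateLaw(
    name="Irreversible mass action",
    parameter_slots=("k",),
    arity=(ANY, ANY),
    reversible_compatible=False,
    kind=MASS_ACTION_IRREVERSIBLE,
)

REVERSIBLE_MASS_ACTION = RateLaw(
    name="Reversible mass action",
    parameter_slots=("kf", "kr"),
    arity=(ANY, ANY),
    reversible_compatible=True,
    kind=MASS_ACTION_REVERSIBLE,
)

IRREVERSIBLE_MICHAELIS_MENTEN = RateLaw(
    name="Irreversible Michaelis-Menten",
    parameter_slots=("V", "Km"),
    arity=(1, 1),
    reversible_compatible=False,
    kind=MICHAELIS_MENTEN_IRREVERSIBLE,
)

REVERSIBLE_MICHAELIS_MENTEN = RateLaw(
    name="Reversible Michaelis-Menten",
    parameter_slots=("Vf", "Vr", "Kms", "Kmp"),
    arity=(1, 1),
    reversible_compatible=True,
    kind=MICHAELIS_MENTEN_REVERSIBLE,
)

COMPETITIVE_INHIBITION_MICHAELIS_MENTEN = RateLaw(
    name="Competitive inhibition Michaelis-Menten",
    parameter_slots=("V", "Km", "Ki"),
    arity=(1, 1),
    reversible_compatible=False,
    kind=MICHAELIS_MENTEN_COMPETITIVE,
)

BUILTIN_LIBRARY: tuple[RateLaw, ...] = (
    IRREVERSIBLE_MASS_ACTION,
    REVERSIBLE_MASS_ACTION,
    IRREVERSIBLE_MICHAELIS_MENTEN,
    REVERSIBLE_MICHAELIS_MENTEN,
    COMPETITIVE_INHIBITION_MICHAELIS_MENTEN,
)

_BY_NAME = {law.name: law for law in BUILTIN_LIBRARY}


def builtin_rate_law(name: str) -> RateLaw:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown built-in rate law {name!r}; available: {sorted(_BY_NAME)}"
        ) from None


def custom_rate_law(
    name: str,
    expression: str,
    parameter_slots: Sequence[str],
    arity: tuple[int, int] = (ANY, ANY),
    reversible_compatible: bool = False,
) -> RateLaw:
    """Define a user rate law over a restricted arithmetic grammar."""
    return RateLaw(
        name=name,
        parameter_slots=tuple(parameter_slots),
        arity=arity,
        reversible_compatible=reversible_compatible,
        kind="custom",
        expression=expression,
    )


def evaluate_rate(
    rate_law: RateLaw,
    concentrations: Mapping[str, float],
    parameters: Mapping[str, float],
    reactants: Optional[Mapping[str, int]] = None,
    products: Optional[Mapping[str, int]] = None,
    inhibitor: Optional[str] = None,
) -> float:
    """Instantaneous reaction velocity of ``rate_law`` at the given state.

    For built-in structural laws the reactant/product stoichiometries
    identify the species entering the formula; for a custom law the
    expression is evaluated directly.  Negative concentrations and
    unbound symbols raise :class:`EvaluationError`.
    """
    for sid, c in concentrations.items():
        if c < 0:
            raise EvaluationError(f"negative concentration for {sid}: {c}")
    if rate_law.kind == "custom":
        expr = rate_law._compiled
    else:
        if reactants is None:
            # every concentration entry is taken to be a reactant with
            # unit stoichiometry
            reactants = {sid: 1 for sid in concentrations}
        expr = Expression(
            rate_law.build_expression(reactants, products or {}, inhibitor)
        )
    env = dict(parameters)
    env.update(concentrations)
    try:
        return expr(env)
    except ExpressionError as exc:
        raise EvaluationError(str(exc)) from exc
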