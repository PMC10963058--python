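"""In-memory representation and editing of kinetic reaction-network models.

A :class:`Model` is the unit of simulation and comparison: compartments,
metabolites (with initial concentrations in nM unless the model declares
otherwise), reactions with stoichiometry and a kinetic rate law, and
global parameters.  Models are edited through methods that preserve
referential integrity; structural snapshots (:meth:`Model.to_dict`)
support JSON round-trips for fixtures and configuration.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from ._expr import Expression
from .errors import (
    ConflictError,
    ConfigurationError,
    EquationParseError,
    IntegrityError,
    LookupErrorKN,
)
from .ratelaws import (
    ANY,
    BUILTIN_LIBRARY,
    RateLaw,
    builtin_rate_law,
    custom_rate_law,
)

MODIFIER_ROLES = ("inhibitor", "activator", "catalyst")


@dataclass
class Metabolite:
    """A chemical species: id, display name, compartment, initial state.

    ``fixed=True`` clamps the concentration (a boundary species); otherwise
    the concentration is governed by the reaction ODEs.
    """

    id: str
    name: str = ""
    compartment: str = "default"
    initial_concentration: float = 0.0
    fixed: bool = False

    def __post_init__(self):
        if not self.name:
            self.name = self.id
        if self.initial_concentration < 0:
            raise IntegrityError(
                f"metabolite {self.id!r}: initial concentration must be >= 0"
            )


@dataclass
class Reaction:
    id: str
    name: str = ""
    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    modifiers: list[tuple[str, str]] = field(default_factory=list)
    reversible: bool = False
    rate_law: Optional[RateLaw] = None
    parameter_values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        if not self.name:
            self.name = self.id
        for role_entry in self.modifiers:
            if role_entry[1] not in MODIFIER_ROLES:
                raise IntegrityError(
                    f"reaction {self.id!r}: unknown modifier role {role_entry[1]!r}"
                )
        for stoich in (self.reactants, self.products):
            for sid, coef in stoich.items():
                if not isinstance(coef, int) or coef <= 0:
                    raise EquationParseError(
                        f"reaction {self.id!r}: stoichiometric coefficient for "
                        f"{sid!r} must be a positive integer, got {coef!r}"
                    )
        if not self.reactants and not self.products:
            raise IntegrityError(
                f"reaction {self.id!r}: reactants and products cannot both be empty"
            )

    @property
    def n_reactants(self) -> int:
        """Reactant count with stoichiometric multiplicity."""
        return sum(self.reactants.values())

    @property
    def n_products(self) -> int:
        return sum(self.products.values())

    def inhibitor(self) -> Optional[str]:
        for sid, role in self.modifiers:
            if role == "inhibitor":
                return sid
        return None

    def rate_expression(self) -> Expression:
        """Compiled concrete formula of this reaction's rate law."""
        if self.rate_law is None:
            raise ConfigurationError(f"reaction {self.id!r} has no rate law")
        return Expression(
            self.rate_law.build_expression(
                self.reactants, self.products, self.inhibitor()
            )
        )


# -- reaction-equation grammar -------------------------------------------------

_ARROWS = ("<->", "->", "=")
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, text: str) -> dict[str, int]:
    side = side.strip()
    if not side:
        return {}
    stoich: dict[str, int] = {}
    for raw in side.split("+"):
        term = raw.strip()
        if not term:
            raise EquationParseError(
                f"dangling '+' in equation {text!r}"
            )
        m = _TERM_RE.match(term)
        if not m:
            raise EquationParseError(
                f"cannot parse term {term!r} in equation {text!r}"
            )
        coef_s, species = m.groups()
        if coef_s is None:
            coef = 1
        else:
            coef_f = float(coef_s)
            if coef_f <= 0 or coef_f != int(coef_f):
                raise EquationParseError(
                    f"coefficient {coef_s!r} for {species!r} must be a "
                    f"positive integer (equation {text!r})"
                )
            coef = int(coef_f)
        stoich[species] = stoich.get(species, 0) + coef
    return stoich


def parse_reaction_equation(text: str) -> tuple[dict[str, int], dict[str, int], bool]:
    """Parse ``"2 A + B <-> C"`` into stoichiometry maps and reversibility.

    ``->`` marks an irreversible reaction; ``<->`` (or ``=``, the common
    SBML-tool synonym) a reversible one.  Omitted coefficients default
    to 1; species names are whitespace-trimmed.  One side may be empty
    (a source or sink).
    """
    for arrow in _ARROWS:
        if arrow in text:
            lhs, _, rhs = text.partition(arrow)
            reversible = arrow in ("<->", "=")
            reactants = _parse_side(lhs, text)
            products = _parse_side(rhs, text)
            if not reactants and not products:
                raise EquationParseError(f"equation {text!r} has no species")
            return reactants, products, reversible
    raise EquationParseError(
        f"equation {text!r} has no arrow ('->', '<->' or '=')"
    )


def suggest_rate_laws(
    reaction: Reaction, library: Sequence[RateLaw] = BUILTIN_LIBRARY
) -> list[RateLaw]:
    """Rate laws applicable to ``reaction``, mass-action variants first.

    A law applies when its arity matches the reaction's reactant/product
    counts (with stoichiometric multiplicity, wildcards allowed) and its
    reversibility flag matches the reaction's.  Order within each group
    follows the library order, so the result is deterministic.
    """
    matching = [
        law
        for law in library
        if law.matches(reaction.n_reactants, reaction.n_products, reaction.reversible)
    ]
    return [law for law in matching if law.is_mass_action] + [
        law for law in matching if not law.is_mass_action
    ]


@dataclass
class Model:
    """A kinetic reaction network: the unit of simulation and comparison."""

    id: str = "model"
    name: str = ""
    compartments: list[tuple[str, float]] = field(default_factory=lambda: [("default", 1.0)])
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    global_parameters: dict[str, float] = field(default_factory=dict)
    concentration_unit: str = "nM"
    time_unit: str = "s"
    #: optional display coordinates (e.g. from KGML graphics blocks)
    layout_hints: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.name:
            self.name = self.id

    # -- lookups ---------------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, sid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == sid:
                return m
        raise LookupErrorKN(f"no metabolite {sid!r} in model {self.id!r}")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise LookupErrorKN(f"no reaction {rid!r} in model {self.id!r}")

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    # -- integrity -------------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity and namespace disjointness."""
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            raise IntegrityError(f"duplicate metabolite ids in model {self.id!r}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            raise IntegrityError(f"duplicate reaction ids in model {self.id!r}")
        if set(mids) & set(rids):
            raise IntegrityError(
                f"metabolite and reaction id namespaces overlap: "
                f"{sorted(set(mids) & set(rids))}"
            )
        known = set(mids)
        comps = {cid for cid, _ in self.compartments}
        for m in self.metabolites:
            if m.compartment not in comps:
                raise IntegrityError(
                    f"metabolite {m.id!r} references unknown compartment "
                    f"{m.compartment!r}"
                )
        for r in self.reactions:
            refs = set(r.reactants) | set(r.products) | {sid for sid, _ in r.modifiers}
            dangling = refs - known
            if dangling:
                raise IntegrityError(
                    f"reaction {r.id!r} references unknown metabolites "
                    f"{sorted(dangling)}"
                )
            if r.rate_law is not None:
                declared = set(r.rate_law.parameter_slots)
                given = set(r.parameter_values)
                if declared != given:
                    raise IntegrityError(
                        f"reaction {r.id!r}: parameter values {sorted(given)} do not "
                        f"cover the rate law's slots {sorted(declared)}"
                    )
                expr = r.rate_expression()
                expr.check_bound(
                    known | declared | set(self.global_parameters) | comps
                )

    def is_parameterized(self) -> bool:
        return all(r.rate_law is not None for r in self.reactions)

    # -- editing ---------------------------------------------------------------

    def add_metabolite(self, metabolite: Metabolite) -> "Model":
        if metabolite.id in self.metabolite_ids or metabolite.id in self.reaction_ids:
            raise ConflictError(f"id {metabolite.id!r} already used in model")
        self.metabolites.append(metabolite)
        return self

    def add_reaction(self, reaction: Reaction) -> "Model":
        if reaction.id in self.reaction_ids or reaction.id in self.metabolite_ids:
            raise ConflictError(f"id {reaction.id!r} already used in model")
        known = set(self.metabolite_ids)
        refs = (
            set(reaction.reactants)
            | set(reaction.products)
            | {sid for sid, _ in reaction.modifiers}
        )
        if refs - known:
            raise IntegrityError(
                f"reaction {reaction.id!r} references unknown metabolites "
                f"{sorted(refs - known)}"
            )
        self.reactions.append(reaction)
        return self

    def remove_reaction(self, rid: str) -> "Model":
        r = self.reaction(rid)
        self.reactions.remove(r)
        return self

    def remove_metabolite(self, sid: str) -> "Model":
        m = self.metabolite(sid)
        users = [
            r.id
            for r in self.reactions
            if sid in r.reactants
            or sid in r.products
            or any(mid == sid for mid, _ in r.modifiers)
        ]
        if users:
            raise IntegrityError(
                f"metabolite {sid!r} is referenced by reactions {users}; "
                f"remove those first"
            )
        self.metabolites.remove(m)
        return self

    def set_parameter(self, path: str, value: float) -> None:
        """Set a value at a parameter path (see :func:`resolve_parameter`)."""
        set_parameter(self, path, value)

    def get_parameter(self, path: str) -> float:
        return get_parameter(self, path)

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        def law_dict(r: Reaction):
            if r.rate_law is None:
                return None
            law = r.rate_law
            d = {"name": law.name, "kind": law.kind}
            if law.kind == "custom":
                d.update(
                    expression=law.expression,
                    parameter_slots=list(law.parameter_slots),
                    arity=list(law.arity),
                    reversible_compatible=law.reversible_compatible,
                )
            return d

        return {
            "id": self.id,
            "name": self.name,
            "concentration_unit": self.concentration_unit,
            "time_unit": self.time_unit,
            "compartments": [[cid, vol] for cid, vol in self.compartments],
            "global_parameters": dict(self.global_parameters),
            "layout_hints": {k: list(v) for k, v in self.layout_hints.items()},
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "initial_concentration": m.initial_concentration,
                    "fixed": m.fixed,
                }
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "reactants": dict(r.reactants),
                    "products": dict(r.products),
                    "modifiers": [list(t) for t in r.modifiers],
                    "reversible": r.reversible,
                    "rate_law": law_dict(r),
                    "parameter_values": dict(r.parameter_values),
                    "provenance": r.provenance,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Model":
        def law_from(ld):
            if ld is None:
                return None
            if ld["kind"] == "custom":
                return custom_rate_law(
                    ld["name"],
                    ld["expression"],
                    ld["parameter_slots"],
                    tuple(ld.get("arity", (ANY, ANY))),
                    ld.get("reversible_compatible", False),
                )
            for law in BUILTIN_LIBRARY:
                if law.kind == ld["kind"]:
                    return law
            raise LookupErrorKN(f"unknown rate-law kind {ld['kind']!r}")

        model = cls(
            id=d["id"],
            name=d.get("name", d["id"]),
            compartments=[tuple(c) for c in d.get("compartments", [("default", 1.0)])],
            global_parameters=dict(d.get("global_parameters", {})),
            concentration_unit=d.get("concentration_unit", "nM"),
            time_unit=d.get("time_unit", "s"),
            layout_hints={
                k: tuple(v) for k, v in d.get("layout_hints", {}).items()
            },
        )
        for md in d.get("metabolites", []):
            model.metabolites.append(
                Metabolite(
                    id=md["id"],
                    name=md.get("name", md["id"]),
                    compartment=md.get("compartment", "default"),
                    initial_concentration=md.get("initial_concentration", 0.0),
                    fixed=md.get("fixed", False),
                )
            )
        for rd in d.get("reactions", []):
            model.reactions.append(
                Reaction(
                    id=rd["id"],
                    name=rd.get("name", rd["id"]),
                    reactants={k: int(v) for k, v in rd.get("reactants", {}).items()},
                    products={k: int(v) for k, v in rd.get("products", {}).items()},
                    modifiers=[tuple(t) for t in rd.get("modifiers", [])],
                    reversible=rd.get("reversible", False),
                    rate_law=law_from(rd.get("rate_law")),
                    parameter_values=dict(rd.get("parameter_values", {})),
                    provenance=dict(rd.get("provenance", {})),
                )
            )
        model.validate()
        return model

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "Model":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))

    def structurally_equal(self, other: "Model") -> bool:
        return self.to_dict() == other.to_dict()


# -- parameter paths -----------------------------------------------------------
#
# A parameter path addresses one tunable value:
#   "global.V1"            — a global parameter
#   "reaction.r1.k"        — a local reaction parameter
#   "metabolite.A.initial" — an initial concentration


def _resolve(model: Model, path: str):
    parts = path.split(".")
    if len(parts) == 2 and parts[0] == "global":
        name = parts[1]
        if name not in model.global_parameters:
            raise LookupErrorKN(f"no global parameter {name!r}")
        return ("global", name)
    if len(parts) == 3 and parts[0] == "reaction":
        r = model.reaction(parts[1])
        if parts[2] not in r.parameter_values:
            raise LookupErrorKN(
                f"reaction {r.id!r} has no parameter {parts[2]!r}"
            )
        return ("reaction", r, parts[2])
    if len(parts) == 3 and parts[0] == "metabolite" and parts[2] == "initial":
        return ("metabolite", model.metabolite(parts[1]))
    raise LookupErrorKN(f"cannot resolve parameter path {path!r}")


def get_parameter(model: Model, path: str) -> float:
    kind, *rest = _resolve(model, path)
    if kind == "global":
        return model.global_parameters[rest[0]]
    if kind == "reaction":
        r, slot = rest
        return r.parameter_values[slot]
    return rest[0].initial_concentration


def set_parameter(model: Model, path: str, value: float) -> None:
    kind, *rest = _resolve(model, path)
    if kind == "global":
        model.global_parameters[rest[0]] = value
    elif kind == "reaction":
        r, slot = rest
        r.parameter_values[slot] = value
    else:
        rest[0].initial_concentration = value
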