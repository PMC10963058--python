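"""SBML read/write for kinetic models.

Reads SBML Level 2/3 into :class:`~kinnet.model.Model` and writes SBML
Level 3 Version 1.  Kinetic laws are carried as explicit formula
expressions; local reaction parameters stay local (renamed with a
reaction-id prefix if they collide with a global symbol).  Events and
algebraic/assignment rules are outside the supported subset and raise
:class:`UnsupportedFeatureError`.
"""

from __future__ import annotations

import logging
import re
import warnings

import libsbml

from ._expr import Expression
from .errors import KinnetError, UnsupportedFeatureError
from .model import Metabolite, Model, Reaction
from .ratelaws import custom_rate_law

log = logging.getLogger(__name__)

_SBO_ROLE = {"inhibitor": 20, "activator": 459, "catalyst": 13}
_ROLE_FROM_SBO = {20: "inhibitor", 537: "inhibitor", 459: "activator",
                  461: "activator", 21: "activator", 13: "catalyst",
                  460: "catalyst"}


class SBMLParseError(KinnetError):
    pass


def _check_document(doc: libsbml.SBMLDocument, path) -> None:
    if doc.getNumErrors() > 0:
        fatal = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        if fatal:
            raise SBMLParseError(f"cannot read {path}: {fatal[0].strip()}")


def _formula_of(math_node) -> str:
    text = libsbml.formulaToL3String(math_node)
    if text is None:
        raise UnsupportedFeatureError("kinetic law has no parseable math")
    return text


_WORD = r"(?<![A-Za-z0-9_]){}(?![A-Za-z0-9_])"


def _rename_symbol(expression: str, old: str, new: str) -> str:
    return re.sub(_WORD.format(re.escape(old)), new, expression)


def read_sbml(path) -> Model:
    """Load an SBML Level 2/3 file into a kinetic model.

    Boundary/constant species become fixed metabolites; reactions with a
    kineticLaw get an expression rate law with their local parameters;
    reactions without one are imported unparameterized (and the model is
    flagged via a warning).
    """
    reader = libsbml.SBMLReader()
    doc = reader.readSBMLFromFile(str(path))
    _check_document(doc, path)
    smodel = doc.getModel()
    if smodel is None:
        raise SBMLParseError(f"{path} contains no model")

    for construct, count in (
        ("events", smodel.getNumEvents()),
        ("rules", smodel.getNumRules()),
        ("constraints", smodel.getNumConstraints()),
    ):
        if count:
            raise UnsupportedFeatureError(
                f"SBML {construct} are not supported ({count} found in {path})"
            )

    model = Model(
        id=smodel.getId() or "model",
        name=smodel.getName() or smodel.getId() or "model",
        compartments=[],
    )
    for i in range(smodel.getNumCompartments()):
        c = smodel.getCompartment(i)
        vol = c.getVolume() if c.isSetVolume() else 1.0
        model.compartments.append((c.getId(), vol))
    if not model.compartments:
        model.compartments.append(("default", 1.0))

    if smodel.isSetSubstanceUnits():
        model.concentration_unit = smodel.getSubstanceUnits()
    if smodel.isSetTimeUnits():
        model.time_unit = smodel.getTimeUnits()

    for i in range(smodel.getNumParameters()):
        p = smodel.getParameter(i)
        model.global_parameters[p.getId()] = p.getValue() if p.isSetValue() else 0.0

    default_comp = model.compartments[0][0]
    for i in range(smodel.getNumSpecies()):
        s = smodel.getSpecies(i)
        if s.isSetInitialConcentration():
            conc = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            comp = smodel.getCompartment(s.getCompartment())
            vol = comp.getVolume() if comp is not None and comp.isSetVolume() else 1.0
            conc = s.getInitialAmount() / vol if vol else s.getInitialAmount()
        else:
            conc = 0.0
        model.metabolites.append(
            Metabolite(
                id=s.getId(),
                name=s.getName() or s.getId(),
                compartment=s.getCompartment() or default_comp,
                initial_concentration=max(conc, 0.0),
                fixed=bool(s.getBoundaryCondition() or s.getConstant()),
            )
        )

    reserved = set(model.global_parameters) | set(model.metabolite_ids)
    unparameterized = []
    for i in range(smodel.getNumReactions()):
        sr = smodel.getReaction(i)
        reactants = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            st = ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            reactants[ref.getSpecies()] = reactants.get(ref.getSpecies(), 0) + int(round(st))
        products = {}
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            st = ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            products[ref.getSpecies()] = products.get(ref.getSpecies(), 0) + int(round(st))
        modifiers = []
        for j in range(sr.getNumModifiers()):
            ref = sr.getModifier(j)
            role = _ROLE_FROM_SBO.get(ref.getSBOTerm(), "catalyst")
            modifiers.append((ref.getSpecies(), role))

        rate_law = None
        parameter_values: dict[str, float] = {}
        if sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            expression = _formula_of(kl.getMath()) if kl.isSetMath() else None
            locals_ = []
            n_local = (
                kl.getNumLocalParameters()
                if hasattr(kl, "getNumLocalParameters") and kl.getNumLocalParameters()
                else kl.getNumParameters()
            )
            for j in range(n_local):
                p = (
                    kl.getLocalParameter(j)
                    if hasattr(kl, "getLocalParameter") and kl.getLocalParameter(j)
                    else kl.getParameter(j)
                )
                locals_.append((p.getId(), p.getValue() if p.isSetValue() else 0.0))
            if expression is not None:
                for pid, value in locals_:
                    slot = pid
                    if pid in reserved:
                        slot = f"{sr.getId()}_{pid}"
                        expression = _rename_symbol(expression, pid, slot)
                    parameter_values[slot] = value
                rate_law = custom_rate_law(
                    name=f"{sr.getId()} kinetics",
                    expression=expression,
                    parameter_slots=list(parameter_values),
                    reversible_compatible=bool(sr.getReversible()),
                )
        if rate_law is None:
            unparameterized.append(sr.getId())
        model.reactions.append(
            Reaction(
                id=sr.getId(),
                name=sr.getName() or sr.getId(),
                reactants=reactants,
                products=products,
                modifiers=modifiers,
                reversible=bool(sr.getReversible()),
                rate_law=rate_law,
                parameter_values=parameter_values,
            )
        )
    if unparameterized:
        warnings.warn(
            f"model {model.id!r} is unparameterized: reactions "
            f"{unparameterized} have no kinetic law",
            stacklevel=2,
        )
    model.validate()
    return model


def write_sbml(model: Model, path) -> None:
    """Write the model as SBML Level 3 Version 1.

    Reactions without a rate law are emitted without a kineticLaw
    element (with a warning); reading the file back yields a model
    structurally equivalent to the input.
    """
    model.validate()
    doc = libsbml.SBMLDocument(3, 1)
    sm = doc.createModel()
    sm.setId(model.id)
    sm.setName(model.name)

    for cid, vol in model.compartments:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)
        c.setSize(vol)
        c.setSpatialDimensions(3)

    for m in model.metabolites:
        s = sm.createSpecies()
        s.setId(m.id)
        s.setName(m.name)
        s.setCompartment(m.compartment)
        s.setInitialConcentration(m.initial_concentration)
        s.setBoundaryCondition(m.fixed)
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)

    for pname, value in model.global_parameters.items():
        p = sm.createParameter()
        p.setId(pname)
        p.setValue(value)
        p.setConstant(True)

    for r in model.reactions:
        sr = sm.createReaction()
        sr.setId(r.id)
        sr.setName(r.name)
        sr.setReversible(r.reversible)
        sr.setFast(False)
        for sid, coef in r.reactants.items():
            ref = sr.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        for sid, coef in r.products.items():
            ref = sr.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        for sid, role in r.modifiers:
            ref = sr.createModifier()
            ref.setSpecies(sid)
            ref.setSBOTerm(_SBO_ROLE[role])
        if r.rate_law is None:
            log.warning("reaction %s written without a kinetic law", r.id)
            continue
        expression = r.rate_law.build_expression(
            r.reactants, r.products, r.inhibitor()
        )
        kl = sr.createKineticLaw()
        math = libsbml.parseL3Formula(expression.replace("**", "^"))
        if math is None:
            raise UnsupportedFeatureError(
                f"cannot render expression {expression!r} as SBML math"
            )
        kl.setMath(math)
        for pname, value in r.parameter_values.items():
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(value)

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise IOError(f"cannot write SBML to {path}")


def _rate_signature(r: Reaction, model: Model, n_points: int = 3) -> list[float]:
    """Evaluate the reaction's concrete rate formula at deterministic
    probe states, for structural comparison across formats."""
    if r.rate_law is None:
        return []
    expr = r.rate_expression()
    sig = []
    species = model.metabolite_ids
    for k in range(1, n_points + 1):
        env = {sid: 0.5 * k + 0.1 * i for i, sid in enumerate(species)}
        env.update(dict(model.compartments))
        env.update(model.global_parameters)
        env.update(r.parameter_values)
        try:
            sig.append(round(expr(env), 9))
        except Exception:
            sig.append(float("nan"))
    return sig


def structurally_equivalent(a: Model, b: Model, sig_digits: int = 12) -> bool:
    """Structural equality across a serialization round-trip.

    Compares ids, stoichiometry, reversibility, fixed flags, initial
    concentrations, global and local parameter values (to ``sig_digits``
    significant digits), and the numerical behaviour of each reaction's
    rate formula at probe states (formula text may be reformatted by the
    round-trip).
    """

    def sig(x: float) -> float:
        return float(f"%.{sig_digits}g" % x)

    def snapshot(m: Model):
        return {
            "metabolites": sorted(
                (mm.id, mm.compartment, sig(mm.initial_concentration), mm.fixed)
                for mm in m.metabolites
            ),
            "globals": sorted((k, sig(v)) for k, v in m.global_parameters.items()),
            "reactions": sorted(
                (
                    r.id,
                    tuple(sorted(r.reactants.items())),
                    tuple(sorted(r.products.items())),
                    tuple(sorted(sid for sid, _ in r.modifiers)),
                    r.reversible,
                    tuple(sorted((k, sig(v)) for k, v in r.parameter_values.items())),
                    tuple(_rate_signature(r, m)),
                )
                for r in m.reactions
            ),
        }

    return snapshot(a) == snapshot(b)
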