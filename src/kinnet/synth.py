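"""Synthetic model generation: random kinetic networks for testing, a
signaling-cascade fixture for the comparative workflows, mutant
construction, and drug-treatment models.

The signaling fixture (:func:`build_signaling_model`) is a synthetic
receptor-driven kinase cascade — receptor expression and ligand-induced
degradation, a GTPase switch, a three-tier phosphorylation cascade, a
parallel kinase arm, and a downstream transcription-cofactor pool whose
degradation is controlled by the unphosphorylated form of its regulator
kinase.  It is built to operate in the regime where healthy-state
phosphorylation is transient/basal while removing the deactivating
reactions leaves it prolonged, so mutant, drug-treatment, and
multi-parameter perturbation studies can run without any external model
download.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import KinnetError, ValidationError
from .model import Metabolite, Model, Reaction
from .ratelaws import (
    IRREVERSIBLE_MASS_ACTION,
    IRREVERSIBLE_MICHAELIS_MENTEN,
    REVERSIBLE_MASS_ACTION,
    custom_rate_law,
)

DEFAULT_LAW_MIX = {
    "mass_action_irreversible": 0.5,
    "mass_action_reversible": 0.3,
    "michaelis_menten_irreversible": 0.2,
}

#: log-uniform parameter ranges for generated models
PARAM_RANGES = {
    "k": (1e-3, 1e-1),  # 1/s (times concentration powers)
    "kf": (1e-3, 1e-1),
    "kr": (1e-3, 1e-1),
    "V": (1e-1, 1e1),  # nM/s
    "Km": (1e0, 1e2),  # nM
}


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_synthetic_model(
    n_metabolites: int,
    n_reactions: int,
    law_mix: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> Model:
    """A random, weakly connected, closed kinetic network.

    Reactions are single-substrate/single-product conversions whose rate
    laws are drawn from ``law_mix`` (mass action irreversible/reversible,
    irreversible Michaelis-Menten); parameters are log-uniform in fixed
    ranges and initial concentrations uniform in [0.5, 10] nM.  The
    network is closed (no sources or sinks), so trajectories stay bounded
    and the model simulates without solver failure.  Deterministic for a
    fixed seed.
    """
    if n_metabolites < 2 or n_reactions < 1:
        raise ValidationError(
            "need n_metabolites >= 2 and n_reactions >= 1"
        )
    mix = dict(DEFAULT_LAW_MIX if law_mix is None else law_mix)
    kinds = list(mix)
    weights = np.array([mix[k] for k in kinds], dtype=float)
    if weights.sum() <= 0:
        raise ValidationError("law_mix proportions must sum to a positive value")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    model = Model(id=f"synthetic_{n_metabolites}m_{n_reactions}r_seed{seed}")
    for i in range(n_metabolites):
        model.add_metabolite(
            Metabolite(
                id=f"M{i}",
                initial_concentration=float(rng.uniform(0.5, 10.0)),
            )
        )

    # guarantee weak connectivity: the first reactions chain every
    # metabolite into the network, later ones connect random pairs
    connected = [0]
    pending = list(range(1, n_metabolites))
    for j in range(n_reactions):
        if pending:
            a = int(rng.choice(connected))
            b = pending.pop(0)
            connected.append(b)
        else:
            a, b = rng.choice(n_metabolites, size=2, replace=False)
            a, b = int(a), int(b)
        kind = str(rng.choice(kinds, p=weights))
        if kind == "mass_action_irreversible":
            law, params = IRREVERSIBLE_MASS_ACTION, {"k": _log_uniform(rng, *PARAM_RANGES["k"])}
            reversible = False
        elif kind == "mass_action_reversible":
            law = REVERSIBLE_MASS_ACTION
            params = {
                "kf": _log_uniform(rng, *PARAM_RANGES["kf"]),
                "kr": _log_uniform(rng, *PARAM_RANGES["kr"]),
            }
            reversible = True
        elif kind == "michaelis_menten_irreversible":
            law = IRREVERSIBLE_MICHAELIS_MENTEN
            params = {
                "V": _log_uniform(rng, *PARAM_RANGES["V"]),
                "Km": _log_uniform(rng, *PARAM_RANGES["Km"]),
            }
            reversible = False
        else:
            raise ValidationError(f"unknown law kind {kind!r} in law_mix")
        model.add_reaction(
            Reaction(
                id=f"r{j}",
                reactants={f"M{a}": 1},
                products={f"M{b}": 1},
                reversible=reversible,
                rate_law=law,
                parameter_values=params,
            )
        )
    # metabolites beyond what the chain could reach (more metabolites than
    # reactions + 1) would be isolated; reject such sizes
    if pending:
        raise ValidationError(
            f"cannot weakly connect {n_metabolites} metabolites with only "
            f"{n_reactions} reactions"
        )
    model.validate()
    return model


# -- the synthetic signaling fixture -------------------------------------------


def _cat(expr: str, slots: Sequence[str], name: str):
    return custom_rate_law(name, expr, slots)


def build_signaling_model() -> Model:
    """Synthetic receptor/kinase-cascade signaling model (healthy state).

    Wiring: ligand-bound receptor pR drives a GTPase switch (Ras-like),
    which phosphorylates the apex kinase (BRaf-like) whose deactivation
    is split over two reactions (r17a, r17b); the cascade continues
    through MEK- and ERK-like tiers.  A parallel arm phosphorylates an
    Akt-like kinase directly from the receptor.  Both terminal kinases
    phosphorylate a GSK3b-like regulator whose *unphosphorylated* form
    degrades a beta-catenin-like pool, so cascade activation causes pool
    accumulation.  Receptor expression is set by the global parameter V1
    and ligand-induced receptor degradation by the global k4, the two
    perturbation targets of the EGFR-mutation studies.

    All concentrations in nM, time in s.
    """
    m = Model(id="signaling_healthy", name="synthetic signaling network (healthy)")
    m.global_parameters = {"V1": 100.0, "k4": 0.2}

    fixed = [("EGF", 100.0)]
    pools = [
        ("EGFR", 100.0), ("pEGFR", 0.0),
        ("Ras", 100.0), ("pRas", 0.0),
        ("BRaf", 100.0), ("pBRaf", 0.0),
        ("MEK", 100.0), ("pMEK", 0.0),
        ("ERK", 100.0), ("pERK", 0.0),
        ("Akt", 100.0), ("pAkt", 0.0),
        ("GSK3b", 100.0), ("pGSK3b", 0.0),
        ("bCatenin", 1.0),
    ]
    for sid, conc in fixed:
        m.add_metabolite(Metabolite(id=sid, initial_concentration=conc, fixed=True))
    for sid, conc in pools:
        m.add_metabolite(Metabolite(id=sid, initial_concentration=conc))

    def rxn(rid, reactants, products, law, params, modifiers=(), name=""):
        m.add_reaction(
            Reaction(
                id=rid,
                name=name or rid,
                reactants=reactants,
                products=products,
                modifiers=list(modifiers),
                rate_law=law,
                parameter_values=params,
            )
        )

    # receptor expression (rate proportional to the expression constant V1)
    rxn("r1", {}, {"EGFR": 1},
        _cat("ksyn * V1", ["ksyn"], "receptor expression"),
        {"ksyn": 1e-5}, name="receptor synthesis")
    # ligand binding / activation
    rxn("r2", {"EGF": 1, "EGFR": 1}, {"pEGFR": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 1e-4}, name="ligand binding")
    # receptor recycling
    rxn("r3", {"pEGFR": 1}, {"EGFR": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 0.01}, name="receptor recycling")
    # ligand-induced receptor degradation (rate constant = global k4)
    rxn("r4", {"pEGFR": 1}, {},
        _cat("k4 * pEGFR", [], "receptor degradation"),
        {}, name="receptor degradation")
    # GTPase switch: basal + receptor-driven activation
    rxn("r5", {"Ras": 1}, {"pRas": 1},
        _cat("(kbasal + kact * pEGFR) * Ras", ["kbasal", "kact"], "GTPase activation"),
        {"kbasal": 1e-3, "kact": 1e-5},
        modifiers=[("pEGFR", "catalyst")], name="GTPase activation")
    rxn("r8b", {"pRas": 1}, {"Ras": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 0.1}, name="GTPase deactivation")
    # apex kinase activation; deactivation split over two reactions
    rxn("r9", {"BRaf": 1}, {"pBRaf": 1},
        _cat("k * pRas * BRaf", ["k"], "apex kinase activation"),
        {"k": 5e-5}, modifiers=[("pRas", "catalyst")], name="BRaf activation")
    rxn("r17a", {"pBRaf": 1}, {"BRaf": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 2.5}, name="BRaf deactivation a")
    rxn("r17b", {"pBRaf": 1}, {"BRaf": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 2.5}, name="BRaf deactivation b")
    # middle tier
    rxn("r10", {"MEK": 1}, {"pMEK": 1},
        _cat("k * pBRaf * MEK", ["k"], "MEK activation"),
        {"k": 1e-3}, modifiers=[("pBRaf", "catalyst")], name="MEK activation")
    rxn("r11", {"pMEK": 1}, {"MEK": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 1.0}, name="MEK deactivation")
    # terminal tier
    rxn("r12", {"ERK": 1}, {"pERK": 1},
        _cat("k * pMEK * ERK", ["k"], "ERK activation"),
        {"k": 1e-3}, modifiers=[("pMEK", "catalyst")], name="ERK activation")
    rxn("r13", {"pERK": 1}, {"ERK": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 0.1}, name="ERK deactivation")
    # parallel kinase arm (receptor-driven)
    rxn("r14", {"Akt": 1}, {"pAkt": 1},
        _cat("(kbasal + kact * pEGFR) * Akt", ["kbasal", "kact"], "Akt activation"),
        {"kbasal": 5e-4, "kact": 1e-5},
        modifiers=[("pEGFR", "catalyst")], name="Akt activation")
    rxn("r15", {"pAkt": 1}, {"Akt": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 0.1}, name="Akt deactivation")
    # regulator kinase phosphorylated by both terminal kinases
    rxn("r18", {"GSK3b": 1}, {"pGSK3b": 1},
        _cat("(kerk * pERK + kakt * pAkt) * GSK3b", ["kerk", "kakt"],
             "regulator phosphorylation"),
        {"kerk": 1e-2, "kakt": 1e-2},
        modifiers=[("pERK", "catalyst"), ("pAkt", "catalyst")],
        name="GSK3b phosphorylation")
    rxn("r19", {"pGSK3b": 1}, {"GSK3b": 1},
        IRREVERSIBLE_MASS_ACTION, {"k": 0.05}, name="GSK3b dephosphorylation")
    # transcription-cofactor pool: constant production, degradation gated
    # by the active (unphosphorylated) regulator
    rxn("r20", {}, {"bCatenin": 1},
        _cat("v", ["v"], "cofactor production"), {"v": 0.1},
        name="bCatenin production")
    rxn("r21", {"bCatenin": 1}, {},
        _cat("k * GSK3b * bCatenin", ["k"], "cofactor degradation"),
        {"k": 1e-3}, modifiers=[("GSK3b", "catalyst")],
        name="bCatenin degradation")

    m.validate()
    return m


def make_mutant(
    model: Model,
    deletions: Sequence[str] = (),
    parameter_overrides: Optional[Mapping[str, float]] = None,
) -> Model:
    """A disease-model variant: reactions removed and/or parameters changed.

    The original model is untouched.  Unknown reaction ids or parameter
    paths raise a lookup error.
    """
    mutant = model.copy()
    for rid in deletions:
        mutant.remove_reaction(rid)  # raises LookupErrorKN if absent
    for path, value in (parameter_overrides or {}).items():
        mutant.set_parameter(path, value)
    mutant.id = f"{model.id}_mutant"
    mutant.name = f"{model.name} (mutant)"
    mutant.validate()
    return mutant


DRUG_MECHANISMS = ("competitive_mm", "reversible_mass_action")


def add_drug(
    model: Model,
    drug_name: str,
    initial_conc: float,
    mechanism: str,
    parameters: Optional[Mapping[str, float]] = None,
    target: str = "pBRaf",
    product: str = "BRaf",
) -> Model:
    """Add an inhibitor metabolite plus one reaction through which it
    facilitates the dephosphorylation of a target phospho-species.

    ``competitive_mm`` uses a Michaelis-Menten form scaled by the drug
    concentration (kcat * D * S / (Km + S)); ``reversible_mass_action``
    a drug-catalyzed reversible conversion (k1*D*S - k2*D*P).  A zero
    drug dose therefore leaves the dynamics identical to the untreated
    model.  Returns a new model with exactly one extra metabolite and
    one extra reaction.
    """
    if mechanism not in DRUG_MECHANISMS:
        raise ValidationError(
            f"unknown mechanism {mechanism!r}; choose from {DRUG_MECHANISMS}"
        )
    model.metabolite(target)
    model.metabolite(product)
    treated = model.copy()
    treated.id = f"{model.id}_{drug_name}"
    treated.name = f"{model.name} + {drug_name}"
    treated.add_metabolite(
        Metabolite(id=drug_name, initial_concentration=initial_conc)
    )
    params = dict(parameters or {})
    if mechanism == "competitive_mm":
        params.setdefault("kcat", 1e-3)
        params.setdefault("Km", 10.0)
        law = custom_rate_law(
            f"{drug_name} inhibition (drug-scaled Michaelis-Menten)",
            f"kcat * {drug_name} * {target} / (Km + {target})",
            list(params),
        )
    else:
        params.setdefault("k1", 1e-4)
        params.setdefault("k2", 1e-6)
        law = custom_rate_law(
            f"{drug_name} inhibition (drug-catalyzed reversible mass action)",
            f"k1 * {drug_name} * {target} - k2 * {drug_name} * {product}",
            list(params),
        )
    treated.add_reaction(
        Reaction(
            id=f"r_{drug_name}",
            name=f"{drug_name}-facilitated dephosphorylation",
            reactants={target: 1},
            products={product: 1},
            modifiers=[(drug_name, "catalyst")],
            reversible=mechanism == "reversible_mass_action",
            rate_law=law,
            parameter_values=params,
        )
    )
    treated.validate()
    return treated
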