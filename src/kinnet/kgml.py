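"""KGML (KEGG pathway XML) parsing, module extraction, and conversion
into kinetic reaction-network models.

A parsed pathway is held as a :class:`PathwayGraph` preserving entries,
reactions, relations, and optional graphics coordinates.  Conversion
into a :class:`~kinnet.model.Model` applies fixed normalization rules:
map-type entries are dropped, entries aliasing the same KEGG compound
are merged, catalyzing gene/enzyme entries become catalyst modifiers,
duplicate reactions (identical substrate/product sets) are merged, and
a missing reaction type defaults to irreversible.  The resulting model
is a topology awaiting parameterization (rate laws unset).

KGML carries no module membership inline; modules are supplied as a
JSON side file mapping module id to a list of reaction ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .errors import IntegrityError, KinnetError, LookupErrorKN
from .model import Metabolite, Model, Reaction


class KGMLParseError(KinnetError):
    pass


@dataclass
class Entry:
    entry_id: str
    kind: str  # compound | gene | enzyme | ortholog | group | map | other
    names: list[str]
    reaction_names: list[str] = field(default_factory=list)
    graphics: Optional[tuple[float, float]] = None
    label: str = ""


@dataclass
class KGMLReaction:
    reaction_id: str
    name: str
    substrates: list[str]  # entry ids
    products: list[str]  # entry ids
    type: str  # reversible | irreversible
    catalysts: list[str] = field(default_factory=list)  # entry ids


@dataclass
class Relation:
    source: str
    target: str
    type: str


@dataclass
class PathwayGraph:
    """Parsed KGML content prior to conversion into a kinetic model."""

    pathway_id: str
    entries: dict[str, Entry] = field(default_factory=dict)
    kgml_reactions: list[KGMLReaction] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    modules: dict[str, set[str]] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)
    title: str = ""

    def load_modules(self, path) -> None:
        """Attach module membership from a JSON side file
        (module id -> list of KGML reaction ids)."""
        with open(path) as fh:
            raw = json.load(fh)
        known = {r.reaction_id for r in self.kgml_reactions} | {
            r.name for r in self.kgml_reactions
        }
        for mid, rids in raw.items():
            missing = [r for r in rids if r not in known]
            if missing:
                raise IntegrityError(
                    f"module {mid!r} lists unknown reactions {missing}"
                )
            resolved = {
                r.reaction_id
                for r in self.kgml_reactions
                if r.reaction_id in rids or r.name in rids
            }
            self.modules[mid] = resolved


def parse_kgml(path) -> PathwayGraph:
    """Parse a KGML file, capturing all entry/reaction/relation records.

    Reactions referencing missing entries are kept but reported in
    ``diagnostics`` rather than silently dropped.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise KGMLParseError(f"cannot parse KGML {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise KGMLParseError(f"{path}: root element is {root.tag!r}, not 'pathway'")

    pg = PathwayGraph(
        pathway_id=root.get("name", "").replace("path:", "") or "pathway",
        title=root.get("title", ""),
    )
    reaction_catalysts: dict[str, list[str]] = {}
    for el in root.findall("entry"):
        eid = el.get("id")
        names = (el.get("name") or "").split()
        graphics = None
        label = ""
        g = el.find("graphics")
        if g is not None:
            label = g.get("name", "").split(",")[0]
            if g.get("x") is not None and g.get("y") is not None:
                graphics = (float(g.get("x")), float(g.get("y")))
        entry = Entry(
            entry_id=eid,
            kind=el.get("type", "other"),
            names=names,
            reaction_names=(el.get("reaction") or "").split(),
            graphics=graphics,
            label=label,
        )
        pg.entries[eid] = entry
        for rname in entry.reaction_names:
            reaction_catalysts.setdefault(rname, []).append(eid)

    for el in root.findall("reaction"):
        rid = el.get("id") or el.get("name")
        name = el.get("name", rid)
        substrates = [s.get("id") for s in el.findall("substrate")]
        products = [p.get("id") for p in el.findall("product")]
        rtype = el.get("type") or "irreversible"
        catalysts = reaction_catalysts.get(name, [])
        for side, ids in (("substrate", substrates), ("product", products)):
            for sid in ids:
                if sid not in pg.entries:
                    pg.diagnostics.append(
                        f"reaction {name} references missing {side} entry {sid!r}"
                    )
                elif pg.entries[sid].kind != "compound":
                    pg.diagnostics.append(
                        f"reaction {name} {side} entry {sid!r} is not a compound"
                    )
        pg.kgml_reactions.append(
            KGMLReaction(
                reaction_id=rid,
                name=name,
                substrates=substrates,
                products=products,
                type=rtype,
                catalysts=catalysts,
            )
        )

    for el in root.findall("relation"):
        pg.relations.append(
            Relation(
                source=el.get("entry1"),
                target=el.get("entry2"),
                type=el.get("type", ""),
            )
        )
    return pg


def extract_module(pg: PathwayGraph, module_id: str) -> PathwayGraph:
    """A sub-pathway containing exactly one module's reactions, the
    compound entries they reference, and relations internal to that set."""
    if module_id not in pg.modules:
        raise LookupErrorKN(
            f"no module {module_id!r}; available: {sorted(pg.modules)}"
        )
    keep_rids = pg.modules[module_id]
    reactions = [r for r in pg.kgml_reactions if r.reaction_id in keep_rids]
    keep_entries: set[str] = set()
    for r in reactions:
        keep_entries.update(r.substrates)
        keep_entries.update(r.products)
        keep_entries.update(r.catalysts)
    sub = PathwayGraph(
        pathway_id=f"{pg.pathway_id}:{module_id}",
        entries={eid: e for eid, e in pg.entries.items() if eid in keep_entries},
        kgml_reactions=reactions,
        relations=[
            rel
            for rel in pg.relations
            if rel.source in keep_entries and rel.target in keep_entries
        ],
        modules={module_id: set(keep_rids)},
        title=pg.title,
    )
    return sub


def _compound_key(entry: Entry) -> str:
    """Canonical id for a compound entry (KEGG accession without prefix)."""
    for name in entry.names:
        if ":" in name:
            return name.split(":", 1)[1]
        return name
    return f"entry{entry.entry_id}"


def convert_kgml_to_model(pg: PathwayGraph) -> Model:
    """Convert a parsed pathway into an unparameterized kinetic model.

    Compound entries become metabolites (initial concentration 0, not
    fixed); each KGML reaction becomes one reaction with stoichiometry 1
    per listed substrate/product; catalyzing gene/enzyme entries are
    attached as catalyst modifiers (merged into one pseudo-metabolite per
    distinct gene/enzyme label).  Raises when no usable reaction remains.
    """
    model = Model(id=pg.pathway_id.replace(":", "_"), name=pg.title or pg.pathway_id)

    entry_to_mid: dict[str, str] = {}
    for eid, entry in pg.entries.items():
        if entry.kind != "compound":
            continue
        mid = _compound_key(entry)
        entry_to_mid[eid] = mid
        if mid not in model.metabolite_ids:
            model.add_metabolite(
                Metabolite(
                    id=mid,
                    name=entry.label or mid,
                    initial_concentration=0.0,
                    fixed=False,
                )
            )
            if entry.graphics:
                model.layout_hints[mid] = entry.graphics

    catalyst_mid: dict[str, str] = {}

    def catalyst_metabolite(eid: str) -> Optional[str]:
        entry = pg.entries.get(eid)
        if entry is None or entry.kind not in ("gene", "enzyme", "ortholog"):
            return None
        key = entry.names[0] if entry.names else f"entry{eid}"
        key = key.split(":", 1)[-1].replace(".", "_")
        if key not in catalyst_mid:
            mid = f"enz_{key}"
            catalyst_mid[key] = mid
            model.add_metabolite(
                Metabolite(id=mid, name=entry.label or key, fixed=True)
            )
            if entry.graphics:
                model.layout_hints[mid] = entry.graphics
        return catalyst_mid[key]

    seen_signatures: dict[tuple, str] = {}
    n_added = 0
    for kr in pg.kgml_reactions:
        subs = sorted({entry_to_mid[e] for e in kr.substrates if e in entry_to_mid})
        prods = sorted({entry_to_mid[e] for e in kr.products if e in entry_to_mid})
        if not subs and not prods:
            continue
        signature = (tuple(subs), tuple(prods))
        if signature in seen_signatures:
            continue
        rid = kr.name.split()[0].split(":")[-1] if kr.name else kr.reaction_id
        if rid in model.reaction_ids or rid in model.metabolite_ids:
            rid = f"{rid}_{kr.reaction_id}"
        modifiers = []
        for eid in kr.catalysts:
            mid = catalyst_metabolite(eid)
            if mid is not None and (mid, "catalyst") not in modifiers:
                modifiers.append((mid, "catalyst"))
        model.add_reaction(
            Reaction(
                id=rid,
                name=kr.name or rid,
                reactants={s: 1 for s in subs},
                products={p: 1 for p in prods},
                modifiers=modifiers,
                reversible=kr.type == "reversible",
            )
        )
        seen_signatures[signature] = rid
        n_added += 1
    if n_added == 0:
        raise KinnetError(
            f"pathway {pg.pathway_id!r} yields no usable reactions"
        )
    model.validate()
    return model
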