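"""Bipartite metabolite/reaction network graphs, styling, layout, export.

Metabolites are circular nodes, reactions square nodes colored blue
(reversible) or red (irreversible).  Substrate edges run metabolite ->
reaction, product edges reaction -> metabolite; inhibitor edges are
dashed red with a T-shaped head.  Comparison overlays replace metabolite
node size/color/visibility with the attributes derived from percentage
changes.  Graphs export to GraphML (all attributes typed) and to static
PNG/SVG images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import networkx as nx

from .compare import NodeStyle
from .errors import KinnetError, LookupErrorKN
from .model import Model

#: default visual constants (the style template)
STYLE = {
    "metabolite_color": "#C0C0C0",
    "reversible_color": "#2B6CB0",  # blue
    "irreversible_color": "#C53030",  # red
    "up_color": "#FF0000",  # red: upregulated
    "down_color": "#00FFFF",  # cyan: downregulated
    "metabolite_size": 40.0,
    "reaction_size": 20.0,
}

COLOR_HEX = {"red": STYLE["up_color"], "cyan": STYLE["down_color"],
             "neutral": STYLE["metabolite_color"]}


@dataclass
class NetworkGraph:
    """A styled bipartite reaction-network graph."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    layout: dict[str, tuple[float, float]] = field(default_factory=dict)

    def copy(self) -> "NetworkGraph":
        return NetworkGraph(graph=self.graph.copy(), layout=dict(self.layout))

    def nodes(self, kind: Optional[str] = None) -> list[str]:
        if kind is None:
            return list(self.graph.nodes)
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == kind]

    def is_bipartite(self) -> bool:
        for u, v in self.graph.edges:
            if self.graph.nodes[u]["kind"] == self.graph.nodes[v]["kind"]:
                return False
        return True


def build_graph(model: Model) -> NetworkGraph:
    """The bipartite graph of a model with the default style template."""
    g = nx.DiGraph()
    for m in model.metabolites:
        g.add_node(
            m.id,
            kind="metabolite",
            label=m.name,
            shape="circle",
            color=STYLE["metabolite_color"],
            size=STYLE["metabolite_size"],
            visible=True,
            pc="",
            reference=math.nan,
            perturbed=math.nan,
        )
    for r in model.reactions:
        g.add_node(
            r.id,
            kind="reaction",
            label=r.name,
            shape="square",
            color=STYLE["reversible_color"] if r.reversible else STYLE["irreversible_color"],
            size=STYLE["reaction_size"],
            visible=True,
            pc="",
            reference=math.nan,
            perturbed=math.nan,
        )
        for sid in r.reactants:
            g.add_edge(sid, r.id, kind="substrate", line_style="solid",
                       color="#555555", arrow_style="arrow", visible=True)
        for sid in r.products:
            g.add_edge(r.id, sid, kind="product", line_style="solid",
                       color="#555555", arrow_style="arrow", visible=True)
        for sid, role in r.modifiers:
            if role == "inhibitor":
                g.add_edge(sid, r.id, kind="modifier-inhibitor",
                           line_style="dashed", color="#FF0000",
                           arrow_style="T", visible=True)
            else:
                g.add_edge(sid, r.id, kind="modifier-other",
                           line_style="dashed", color="#888888",
                           arrow_style="arrow", visible=True)
    ng = NetworkGraph(graph=g)
    for nid, xy in model.layout_hints.items():
        if nid in g:
            ng.layout[nid] = tuple(xy)
    return ng


def apply_comparison_overlay(g: NetworkGraph, styles: Sequence[NodeStyle]) -> NetworkGraph:
    """Restyle metabolite nodes per the comparison-derived attributes.

    Reaction nodes are untouched; edges incident to invisible nodes are
    hidden.  Topology (node and edge sets) never changes.
    """
    out = g.copy()
    for style in styles:
        if style.metabolite_id not in out.graph:
            raise LookupErrorKN(
                f"style references unknown node {style.metabolite_id!r}"
            )
        node = out.graph.nodes[style.metabolite_id]
        if node["kind"] != "metabolite":
            raise LookupErrorKN(
                f"{style.metabolite_id!r} is not a metabolite node"
            )
        pc = style.tooltip[0]
        node.update(
            size=style.size,
            color=COLOR_HEX[style.color],
            visible=style.visible,
            pc="inf" if math.isinf(pc) else f"{pc:.10g}",
            reference=style.tooltip[1],
            perturbed=style.tooltip[2],
        )
    for u, v, d in out.graph.edges(data=True):
        d["visible"] = bool(
            out.graph.nodes[u].get("visible", True)
            and out.graph.nodes[v].get("visible", True)
        )
    return out


def clear_overlay(g: NetworkGraph) -> NetworkGraph:
    """Restore the base style template on all metabolite nodes."""
    out = g.copy()
    for n, d in out.graph.nodes(data=True):
        if d["kind"] == "metabolite":
            d.update(
                size=STYLE["metabolite_size"],
                color=STYLE["metabolite_color"],
                visible=True,
                pc="",
                reference=math.nan,
                perturbed=math.nan,
            )
    for _, _, d in out.graph.edges(data=True):
        d["visible"] = True
    return out


def layout_graph(
    g: NetworkGraph,
    method: Literal["force_directed", "hierarchical", "kgml_hint"] = "force_directed",
    seed: int = 0,
) -> NetworkGraph:
    """Assign coordinates to every node; deterministic for a fixed seed.

    ``kgml_hint`` uses stored pathway coordinates where available and
    falls back to force-directed placement otherwise.
    """
    out = g.copy()
    nodes = list(out.graph.nodes)
    if not nodes:
        out.layout = {}
        return out
    if method == "kgml_hint" and set(out.layout) >= set(nodes):
        return out
    if method == "hierarchical":
        # layer nodes by longest-path depth in the (cycle-collapsed) graph
        order = {}
        condensed = nx.condensation(out.graph)
        for layer, scc in enumerate(nx.topological_sort(condensed)):
            for n in condensed.nodes[scc]["members"]:
                order[n] = layer
        counts: dict[int, int] = {}
        pos = {}
        for n in nodes:
            layer = order[n]
            k = counts.get(layer, 0)
            counts[layer] = k + 1
            pos[n] = (float(layer), float(-k))
    else:
        pos = nx.spring_layout(out.graph, seed=seed)
        pos = {n: (float(x), float(y)) for n, (x, y) in pos.items()}
    if method == "kgml_hint":
        pos.update(out.layout)  # hints win where present
    out.layout = pos
    return out


def export_graph(
    g: NetworkGraph,
    format: Literal["graphml", "png", "svg"],
    path,
) -> None:
    """Write the graph as GraphML (typed attributes) or a static image."""
    if format == "graphml":
        gx = g.graph.copy()
        for n, xy in g.layout.items():
            gx.nodes[n]["x"], gx.nodes[n]["y"] = float(xy[0]), float(xy[1])
        nx.write_graphml(gx, str(path))
        return
    if format in ("png", "svg"):
        if g.graph.number_of_nodes() and not g.layout:
            raise KinnetError("assign a layout before image export")
        _render_image(g, path, format)
        return
    raise KinnetError(f"unknown export format {format!r}")


def read_graphml(path) -> NetworkGraph:
    gx = nx.read_graphml(str(path))
    ng = NetworkGraph(graph=nx.DiGraph(gx))
    for n, d in ng.graph.nodes(data=True):
        if "x" in d and "y" in d:
            ng.layout[n] = (d["x"], d["y"])
    return ng


def _render_image(g: NetworkGraph, path, format: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    ax.set_axis_off()
    visible_nodes = {
        n for n, d in g.graph.nodes(data=True) if d.get("visible", True)
    }
    for u, v, d in g.graph.edges(data=True):
        if not d.get("visible", True) or u not in visible_nodes or v not in visible_nodes:
            continue
        x1, y1 = g.layout[u]
        x2, y2 = g.layout[v]
        ls = "--" if d.get("line_style") == "dashed" else "-"
        color = d.get("color", "#555555")
        if d.get("arrow_style") == "T":
            ax.plot([x1, x2], [y1, y2], ls, color=color, lw=1.2)
            # T-bar head perpendicular to the edge at the target end
            dx, dy = x2 - x1, y2 - y1
            norm = math.hypot(dx, dy) or 1.0
            px, py = -dy / norm, dx / norm
            bar = 0.03 * norm
            ax.plot(
                [x2 - px * bar, x2 + px * bar],
                [y2 - py * bar, y2 + py * bar],
                "-",
                color=color,
                lw=1.8,
            )
        else:
            ax.annotate(
                "",
                xy=(x2, y2),
                xytext=(x1, y1),
                arrowprops=dict(
                    arrowstyle="-|>",
                    color=color,
                    ls=ls,
                    shrinkA=6,
                    shrinkB=6,
                ),
            )
    for n, d in g.graph.nodes(data=True):
        if n not in visible_nodes:
            continue
        x, y = g.layout[n]
        marker = "s" if d.get("shape") == "square" else "o"
        ax.scatter(
            [x], [y], s=d.get("size", 30.0), marker=marker,
            c=d.get("color", "#C0C0C0"), edgecolors="black", zorder=3,
        )
        ax.annotate(
            d.get("label", n), (x, y), textcoords="offset points",
            xytext=(0, 7), fontsize=7, ha="center",
        )
    fig.savefig(str(path), format=format, bbox_inches="tight", dpi=150)
    plt.close(fig)
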