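"""Scenario specifications and the end-to-end comparison pipeline.

A scenario names a reference state and a perturbed state — either two
models, or one model plus parameter-scan items — simulates both,
computes per-metabolite percentage changes, derives the visual overlay,
and exports TSV/JSON/GraphML/image outputs.  Scenario outputs are fully
regenerable from the serialized spec (provenance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from .compare import (
    ComparisonResult,
    compare_models,
    derive_node_styles,
    perturbation_compare,
)
from .errors import KinnetError, ValidationError
from .model import Model
from .simulate import DEFAULT_N_POINTS, ScanItem
from .viz import apply_comparison_overlay, build_graph, export_graph, layout_graph

log = logging.getLogger(__name__)

SCENARIO_NAMES = (
    "healthy_vs_disease",
    "healthy_vs_treated",
    "disease_vs_treated",
    "single_perturbation",
    "multi_perturbation",
)


@dataclass
class ScenarioSpec:
    """A reproducible comparative-analysis run."""

    name: str
    reference_model: str  # path to a model JSON/SBML file
    perturbed_model: Optional[str] = None
    scan_items: Optional[list[ScanItem]] = None
    mode: Literal["timecourse_final", "steadystate"] = "timecourse_final"
    duration: float = 15000.0
    n_points: int = DEFAULT_N_POINTS
    outputs: dict[str, str] = field(default_factory=dict)  # tsv/json/graphml/png/svg
    layout_seed: int = 0
    visibility_threshold: float = 1e-6

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValidationError(
                f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}"
            )
        if (self.perturbed_model is None) == (self.scan_items is None):
            raise ValidationError(
                "exactly one of perturbed_model / scan_items must be set"
            )

    def to_json(self, path=None) -> str:
        doc = {
            "name": self.name,
            "reference_model": self.reference_model,
            "perturbed_model": self.perturbed_model,
            "scan_items": (
                None
                if self.scan_items is None
                else [
                    [it.target, it.initial_value, it.final_value]
                    for it in self.scan_items
                ]
            ),
            "mode": self.mode,
            "duration": self.duration,
            "n_points": self.n_points,
            "outputs": self.outputs,
            "layout_seed": self.layout_seed,
            "visibility_threshold": self.visibility_threshold,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ScenarioSpec":
        doc = json.loads(Path(source).read_text()) if not str(source).lstrip().startswith("{") else json.loads(source)
        items = doc.get("scan_items")
        return cls(
            name=doc["name"],
            reference_model=doc["reference_model"],
            perturbed_model=doc.get("perturbed_model"),
            scan_items=None if items is None else [ScanItem(*it) for it in items],
            mode=doc.get("mode", "timecourse_final"),
            duration=doc.get("duration", 15000.0),
            n_points=doc.get("n_points", DEFAULT_N_POINTS),
            outputs=doc.get("outputs", {}),
            layout_seed=doc.get("layout_seed", 0),
            visibility_threshold=doc.get("visibility_threshold", 1e-6),
        )


def load_model(path) -> Model:
    """Load a model from JSON or SBML, by extension."""
    p = Path(path)
    if p.suffix.lower() in (".xml", ".sbml"):
        from .sbml import read_sbml

        return read_sbml(p)
    return Model.from_json(p)


def run_scenario(spec: ScenarioSpec) -> dict:
    """Execute load -> simulate -> compare -> style -> export; return a summary.

    Every stage is logged; errors carry the failing stage in their
    message.  The summary reports the number of changed metabolites and
    the largest up/down deviations.
    """
    stage = "load"
    try:
        ref = load_model(spec.reference_model)
        log.info("scenario %s: loaded reference %s", spec.name, ref.id)
        if spec.perturbed_model is not None:
            pert = load_model(spec.perturbed_model)
            log.info("scenario %s: loaded perturbed %s", spec.name, pert.id)

        stage = "simulate/compare"
        if spec.perturbed_model is not None:
            cr = compare_models(
                ref, pert, spec.mode, spec.duration, spec.n_points
            )
        else:
            cr = perturbation_compare(
                ref, spec.scan_items or [], spec.mode, spec.duration, spec.n_points
            )
        log.info("scenario %s: compared %d metabolites", spec.name, len(cr.pc))

        stage = "style"
        styles = derive_node_styles(
            cr, visibility_threshold=spec.visibility_threshold
        )
        display = pert if spec.perturbed_model is not None else ref
        graph = build_graph(display)
        overlay_styles = [s for s in styles if s.metabolite_id in graph.graph]
        graph = apply_comparison_overlay(graph, overlay_styles)
        graph = layout_graph(graph, "force_directed", seed=spec.layout_seed)

        stage = "export"
        written = {}
        for kind, path in spec.outputs.items():
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            if kind == "tsv":
                cr.to_tsv(path)
            elif kind == "json":
                cr.to_json(path, styles=styles)
            elif kind == "graphml":
                export_graph(graph, "graphml", path)
            elif kind in ("png", "svg"):
                export_graph(graph, kind, path)
            else:
                raise ValidationError(f"unknown output kind {kind!r}")
            written[kind] = str(path)
            log.info("scenario %s: wrote %s -> %s", spec.name, kind, path)
    except KinnetError as exc:
        raise KinnetError(f"scenario {spec.name!r} failed at stage {stage}: {exc}") from exc

    return summarize(spec, cr, written)


def summarize(spec: ScenarioSpec, cr: ComparisonResult, written: dict) -> dict:
    import math

    changed = [
        (mid, pc)
        for mid, pc in zip(cr.metabolite_ids, cr.pc)
        if math.isinf(pc) or abs(pc) >= spec.visibility_threshold
    ]
    unchanged = [
        mid
        for mid, pc in zip(cr.metabolite_ids, cr.pc)
        if not math.isinf(pc) and abs(pc) < spec.visibility_threshold
    ]
    finite = [(m, p) for m, p in changed if not math.isinf(p)]
    return {
        "scenario": spec.name,
        "mode": cr.mode,
        "comparison_time": cr.comparison_time,
        "n_metabolites": len(cr.pc),
        "n_changed": len(changed),
        "n_unchanged": len(unchanged),
        "unchanged": unchanged,
        "max_upregulation": max(
            (p for _, p in finite if p > 0), default=0.0
        ),
        "max_downregulation": min(
            (p for _, p in finite if p < 0), default=0.0
        ),
        "changed": {m: ("inf" if math.isinf(p) else p) for m, p in changed},
        "outputs": written,
    }
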