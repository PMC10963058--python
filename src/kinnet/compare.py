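"""Comparative analysis between two biological states.

Given a reference output A and a perturbed output B (final time-course
concentrations or steady states), the per-metabolite deviation statistic
is the percentage change

    PC_i = 100 * (B_i - A_i) / A_i

which is then mapped onto node visual attributes: upregulated
metabolites red, downregulated cyan, size log-scaled with |PC|, and
unchanged metabolites invisible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd

from .errors import ComparisonError, KinnetError
from .model import Model
from .simulate import (
    DEFAULT_N_POINTS,
    ScanItem,
    find_steady_state,
    parameter_scan,
    simulate_time_course,
)

#: sentinel for an infinite percentage change (reference value was zero)
PC_INFINITE = math.inf

#: |PC| below this (in %) counts as "did not vary" and the node is hidden
DEFAULT_VISIBILITY_THRESHOLD = 1e-6


def percentage_change(a: float, b: float) -> float:
    """PC = 100 * (b - a) / a, with conventions for a zero reference.

    a=0, b=0 -> 0; a=0, b>0 -> +infinity sentinel (maximum node size).
    Negative concentrations are a domain error.
    """
    a, b = float(a), float(b)
    if a < 0 or b < 0:
        raise ComparisonError(f"concentrations must be non-negative, got ({a}, {b})")
    if a == 0:
        return 0.0 if b == 0 else PC_INFINITE
    return 100.0 * (b - a) / a


def format_pc(pc: float) -> str:
    return "∞" if math.isinf(pc) else f"{pc:.6g}"


@dataclass
class ComparisonResult:
    """Per-metabolite percentage changes between two states."""

    metabolite_ids: list[str]
    reference_values: list[float]
    perturbed_values: list[float]
    pc: list[float]
    mode: Literal["timecourse_final", "steadystate"]
    comparison_time: Optional[float] = None
    unmatched_reference: list[str] = field(default_factory=list)
    unmatched_perturbed: list[str] = field(default_factory=list)

    def pc_of(self, metabolite_id: str) -> float:
        try:
            return self.pc[self.metabolite_ids.index(metabolite_id)]
        except ValueError:
            raise ComparisonError(f"no metabolite {metabolite_id!r} in comparison")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": self.metabolite_ids,
                "reference": self.reference_values,
                "perturbed": self.perturbed_values,
                "pc": self.pc,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None, styles: Optional[Sequence["NodeStyle"]] = None) -> str:
        doc = {
            "mode": self.mode,
            "comparison_time": self.comparison_time,
            "metabolites": [
                {
                    "id": mid,
                    "reference": a,
                    "perturbed": b,
                    "pc": (None if math.isinf(p) else p),
                    "pc_display": format_pc(p),
                }
                for mid, a, b, p in zip(
                    self.metabolite_ids,
                    self.reference_values,
                    self.perturbed_values,
                    self.pc,
                )
            ],
            "unmatched_reference": self.unmatched_reference,
            "unmatched_perturbed": self.unmatched_perturbed,
        }
        if styles is not None:
            doc["styles"] = [s.to_dict() for s in styles]
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class NodeStyle:
    """Visual attributes encoding one metabolite's deviation."""

    metabolite_id: str
    size: float
    color: Literal["red", "cyan", "neutral"]
    visible: bool
    tooltip: tuple[float, float, float]  # (PC, reference, perturbed)

    def to_dict(self) -> dict:
        pc = self.tooltip[0]
        return {
            "metabolite_id": self.metabolite_id,
            "size": self.size,
            "color": self.color,
            "visible": self.visible,
            "pc": (None if math.isinf(pc) else pc),
            "pc_display": format_pc(pc),
            "reference": self.tooltip[1],
            "perturbed": self.tooltip[2],
        }


def intersect_elements(ref: Model, pert: Model) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Match metabolites between two models, by id first, then by name.

    Returns (matched id pairs in reference order, unmatched reference ids,
    unmatched perturbed ids).  Raises when the intersection is empty, or
    when name-matching is ambiguous (duplicate display names).
    """
    pert_ids = set(pert.metabolite_ids)
    pairs: list[tuple[str, str]] = []
    used_pert: set[str] = set()
    unmatched_ref: list[str] = []
    for m in ref.metabolites:
        if m.id in pert_ids:
            pairs.append((m.id, m.id))
            used_pert.add(m.id)
        else:
            unmatched_ref.append(m.id)

    # second pass: name matching for still-unmatched reference metabolites
    name_index: dict[str, list[str]] = {}
    for pm in pert.metabolites:
        if pm.id not in used_pert:
            name_index.setdefault(pm.name, []).append(pm.id)
    still_unmatched = []
    for rid in unmatched_ref:
        name = ref.metabolite(rid).name
        candidates = name_index.get(name, [])
        if len(candidates) > 1:
            raise ComparisonError(
                f"ambiguous name match for {rid!r}: candidates {candidates}"
            )
        if candidates:
            pid = candidates[0]
            pairs.append((rid, pid))
            used_pert.add(pid)
            name_index[name] = []
        else:
            still_unmatched.append(rid)
    unmatched_pert = [m.id for m in pert.metabolites if m.id not in used_pert]

    if not pairs:
        raise ComparisonError(
            "models share no metabolites; comparison requires intersecting elements"
        )
    # keep reference order (id matches already are; name matches appended)
    order = {m.id: i for i, m in enumerate(ref.metabolites)}
    pairs.sort(key=lambda p: order[p[0]])
    return pairs, still_unmatched, unmatched_pert


def _final_values(model: Model, mode, duration, n_points, rel_tol, abs_tol):
    if mode == "timecourse_final":
        traj = simulate_time_course(model, duration, n_points, rel_tol, abs_tol)
        return traj.final_state(), float(traj.times[-1])
    if mode == "steadystate":
        ss = find_steady_state(model, rel_tol=rel_tol, abs_tol=abs_tol)
        if ss.status != "found":
            raise ComparisonError(
                f"no steady state found for model {model.id!r}"
            )
        return ss.concentrations, None
    raise ComparisonError(f"unknown comparison mode {mode!r}")


def compare_models(
    ref: Model,
    pert: Model,
    mode: Literal["timecourse_final", "steadystate"] = "timecourse_final",
    duration: float = 100.0,
    n_points: int = DEFAULT_N_POINTS,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-12,
) -> ComparisonResult:
    """Simulate both models sequentially and compute per-metabolite PCs.

    A values come from the reference model, B values from the perturbed
    model, over their metabolite intersection; time-course mode compares
    the final sampled time of a common duration.
    """
    pairs, un_ref, un_pert = intersect_elements(ref, pert)
    a_state, t = _final_values(ref, mode, duration, n_points, rel_tol, abs_tol)
    b_state, _ = _final_values(pert, mode, duration, n_points, rel_tol, abs_tol)
    ids = [rid for rid, _ in pairs]
    a = [float(a_state[rid]) for rid, _ in pairs]
    b = [float(b_state[pid]) for _, pid in pairs]
    return ComparisonResult(
        metabolite_ids=ids,
        reference_values=a,
        perturbed_values=b,
        pc=[percentage_change(x, y) for x, y in zip(a, b)],
        mode=mode,
        comparison_time=t,
        unmatched_reference=un_ref,
        unmatched_perturbed=un_pert,
    )


def perturbation_compare(
    model: Model,
    items: Sequence[ScanItem],
    mode: Literal["timecourse_final", "steadystate"] = "timecourse_final",
    duration: float = 100.0,
    n_points: int = DEFAULT_N_POINTS,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-12,
) -> ComparisonResult:
    """Percentage changes of one model's perturbed state vs its initial state.

    Wraps the parameter scan: A is the baseline output (all scan items at
    their initial value), B the perturbed output (all at their final
    value).  The model is restored afterwards.
    """
    scan_mode = "timecourse" if mode == "timecourse_final" else "steadystate"
    baseline, perturbed = parameter_scan(
        model, items, scan_mode, duration, n_points, rel_tol, abs_tol
    )
    if mode == "timecourse_final":
        a_state, b_state = baseline.final_state(), perturbed.final_state()
        t = float(baseline.times[-1])
    else:
        for out, label in ((baseline, "baseline"), (perturbed, "perturbed")):
            if out.status != "found":
                raise ComparisonError(f"no steady state found for {label} state")
        a_state, b_state = baseline.concentrations, perturbed.concentrations
        t = None
    ids = model.metabolite_ids
    a = [float(a_state[i]) for i in ids]
    b = [float(b_state[i]) for i in ids]
    return ComparisonResult(
        metabolite_ids=list(ids),
        reference_values=a,
        perturbed_values=b,
        pc=[percentage_change(x, y) for x, y in zip(a, b)],
        mode=mode,
        comparison_time=t,
    )


def derive_node_styles(
    cr: ComparisonResult,
    size_min: float = 20.0,
    size_max: float = 100.0,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> list[NodeStyle]:
    """Map percentage changes to node size, color, and visibility.

    Size grows log-compressed with |PC| up to the largest finite |PC| in
    the comparison (PCs can span many orders of magnitude); an infinite
    PC takes the maximum size.  Positive PC is red, negative cyan;
    |PC| below the visibility threshold hides the node.
    """
    if not size_min < size_max:
        raise KinnetError("size_min must be < size_max")
    if visibility_threshold < 0:
        raise KinnetError("visibility_threshold must be >= 0")
    finite = [abs(p) for p in cr.pc if not math.isinf(p)]
    pc_cap = max(finite) if finite else 0.0
    log_cap = math.log10(1.0 + pc_cap)
    styles = []
    for mid, a, b, p in zip(
        cr.metabolite_ids, cr.reference_values, cr.perturbed_values, cr.pc
    ):
        visible = abs(p) >= visibility_threshold if not math.isinf(p) else True
        if not visible or p == 0:
            color = "neutral"
        else:
            color = "red" if p > 0 else "cyan"
        if math.isinf(p):
            size = size_max
        elif log_cap == 0:
            size = size_min
        else:
            frac = min(1.0, math.log10(1.0 + abs(p)) / log_cap)
            size = size_min + (size_max - size_min) * frac
        styles.append(
            NodeStyle(
                metabolite_id=mid,
                size=size,
                color=color,
                visible=visible,
                tooltip=(p, a, b),
            )
        )
    return styles
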