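"""Functional consequences of plugging: resistance score (RS) and OLVP.

The airway tree is converted into a resistor network: each branch ``n`` is a
Poiseuille element ``R_n = 8 * mu * L_n / (pi * r_n**4)`` between its
proximal and distal nodes. A driving pressure ``dP`` is applied at the
tracheal inlet, open terminal outlets sit at pressure 0, and plugged
terminal branches are removed (their outlet carries no flow). Solving the
nodal pressure system yields the total inlet flow ``Q`` and the effective
resistance ``R_eff = dP / Q``. The resistance score compares the tree with
and without plugs:

    RS = 100 * (R_p - R_a) / R_a   [percent]

RS is a "virtual plug extraction": it is independent of ``mu`` and ``dP``
(both cancel in the ratio) and infinite when every outlet is plugged.

The obstructed lung volume percentage assigns every parenchymal voxel to the
nearest airway termination point *within its lobe* and labels it obstructed
when that terminal branch is plugged:

    OLVP = 100 * V_o / V_t   per lobe, aggregated over lobes for the lung.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .tree import GENERATION_GROUPS, AirwayTree, PlugMap
from .volume import CTVolume

__all__ = [
    "FlowConfig",
    "ResistanceResult",
    "OlvpResult",
    "segment_resistance",
    "effective_resistance",
    "resistance_score",
    "rs_per_plug_by_group",
    "olvp",
]

MM_TO_M = 1e-3


@dataclass
class FlowConfig:
    """Fluid constants; defaults are humidified air at body temperature."""

    viscosity: float = 1.85e-5  # Pa*s
    driving_pressure: float = 1.0  # Pa

    def validate(self) -> None:
        if self.viscosity <= 0 or self.driving_pressure <= 0:
            raise ValueError("viscosity and driving pressure must be positive")


@dataclass
class ResistanceResult:
    """Effective resistances with and without plugs, flows, and RS."""

    resistance_unplugged: float  # R_a, Pa*s/m^3
    resistance_plugged: float  # R_p, Pa*s/m^3 (inf when all outlets plugged)
    flow_unplugged: float  # Q_a, m^3/s
    flow_plugged: float  # Q_p, m^3/s
    resistance_score: float  # percent; nan when infinite_flag
    infinite_flag: bool

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "R_a_pa_s_per_m3": self.resistance_unplugged,
            "R_p_pa_s_per_m3": None if self.infinite_flag else self.resistance_plugged,
            "Q_a_m3_per_s": self.flow_unplugged,
            "Q_p_m3_per_s": self.flow_plugged,
            "RS_percent": None if self.infinite_flag else self.resistance_score,
            "infinite_flag": self.infinite_flag,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class OlvpResult:
    """Per-lobe and whole-lung obstructed volume percentages."""

    per_lobe: dict[str, dict[str, float]]  # lobe -> {V_o, V_t, OLVP}
    whole_lung_olvp: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"per_lobe": self.per_lobe, "whole_lung_OLVP_percent": self.whole_lung_olvp},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def segment_resistance(length_mm: float, radius_mm: float, config: FlowConfig | None = None) -> float:
    """Poiseuille resistance of one branch, in Pa*s/m^3 (inputs in mm)."""
    config = config or FlowConfig()
    config.validate()
    if length_mm <= 0 or radius_mm <= 0:
        raise ValueError("branch length and radius must be positive")
    return 8.0 * config.viscosity * (length_mm * MM_TO_M) / (math.pi * (radius_mm * MM_TO_M) ** 4)


def effective_resistance(
    tree: AirwayTree,
    plugged_terminals: Iterable[int] = (),
    config: FlowConfig | None = None,
) -> tuple[float, float, bool]:
    """Effective tree resistance ``(R_eff, Q, infinite_flag)`` for one scenario.

    Node pressures solve Kirchhoff balance with the inlet held at the
    driving pressure, open terminal outlets at 0, and plugged terminal
    branches removed (a natural zero-flow boundary). When every outlet is
    plugged no flow path exists and the infinite flag is raised.
    """
    config = config or FlowConfig()
    config.validate()
    plugged = set(int(b) for b in plugged_terminals)
    terminals = set(tree.terminal_ids)
    if not plugged <= terminals:
        raise ValueError(f"plugged set contains non-terminal branches: {sorted(plugged - terminals)}")
    open_terminals = terminals - plugged
    if not open_terminals:
        return math.inf, 0.0, True

    # Node model: node b = distal end of branch b; inlet node = -1 (root start).
    active = [b for b in sorted(tree.branches) if b not in plugged]
    conduct = {}
    for b in active:
        br = tree.branches[b]
        conduct[b] = 1.0 / segment_resistance(br.length, br.radius, config)

    dirichlet = {-1: config.driving_pressure}
    for b in open_terminals:
        dirichlet[b] = 0.0
    unknowns = [b for b in active if b not in dirichlet]
    pos = {b: i for i, b in enumerate(unknowns)}

    n = len(unknowns)
    A = np.zeros((n, n))
    rhs = np.zeros(n)

    def add_edge(node_u: int, node_v: int, g: float) -> None:
        for a, bnode in ((node_u, node_v), (node_v, node_u)):
            if a in pos:
                A[pos[a], pos[a]] += g
                if bnode in pos:
                    A[pos[a], pos[bnode]] -= g
                else:
                    rhs[pos[a]] += g * dirichlet[bnode]

    for b in active:
        parent = tree.branches[b].parent_id
        upstream = -1 if parent is None else parent
        add_edge(upstream, b, conduct[b])

    if n:
        try:
            p_unknown = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError("pressure system is singular for a partially plugged tree") from exc
    else:
        p_unknown = np.zeros(0)

    def pressure(node: int) -> float:
        if node in dirichlet:
            return dirichlet[node]
        return float(p_unknown[pos[node]])

    root = tree.root_id
    q = conduct[root] * (dirichlet[-1] - pressure(root))
    if q <= 0:
        return math.inf, 0.0, True
    return config.driving_pressure / q, q, False


def resistance_score(
    tree: AirwayTree, plug_map: PlugMap, config: FlowConfig | None = None
) -> ResistanceResult:
    """RS from a plug map: plugged outlets are terminals holding >= 1 plug."""
    config = config or FlowConfig()
    plugged = plug_map.plugged_branch_ids
    r_a, q_a, inf_a = effective_resistance(tree, (), config)
    if inf_a:
        raise RuntimeError("tree carries no open outlets even without plugs")
    r_p, q_p, inf_p = effective_resistance(tree, plugged, config)
    rs = math.nan if inf_p else 100.0 * (r_p - r_a) / r_a
    return ResistanceResult(
        resistance_unplugged=r_a,
        resistance_plugged=r_p,
        flow_unplugged=q_a,
        flow_plugged=q_p,
        resistance_score=rs,
        infinite_flag=inf_p,
    )


def rs_per_plug_by_group(
    tree: AirwayTree, plug_map: PlugMap, config: FlowConfig | None = None
) -> dict[str, float]:
    """RS per plug for each generation group, plugging only that group.

    For group g, the RS is recomputed with only the group's plugs applied
    and divided by the group's plug count; groups without plugs are omitted.
    """
    config = config or FlowConfig()
    out: dict[str, float] = {}
    df = plug_map.assignments
    for group in GENERATION_GROUPS:
        sub = df[df["group"] == group]
        if sub.empty:
            continue
        partial = PlugMap(scan_id=plug_map.scan_id, assignments=sub)
        result = resistance_score(tree, partial, config)
        out[group] = (
            math.inf if result.infinite_flag else result.resistance_score / len(sub)
        )
    return out


def olvp(volume: CTVolume, tree: AirwayTree, plug_map: PlugMap) -> OlvpResult:
    """Obstructed lung volume percentage, per lobe and for the whole lung.

    Every labeled voxel is assigned to the nearest termination point among
    the terminals of its own lobe; it is obstructed when that terminal
    branch holds a plug. Lobes present in the label map but lacking
    terminations raise, naming the lobe.
    """
    if volume.lobe_labels is None or volume.lobe_legend is None:
        raise ValueError("volume lacks lobe labels")
    plugged = plug_map.plugged_branch_ids
    term_ids, term_pts = tree.termination_points()
    term_lobes = np.array([tree.branches[int(i)].lobe for i in term_ids])
    voxel_vol = volume.voxel_volume

    per_lobe: dict[str, dict[str, float]] = {}
    total_vo = total_vt = 0.0
    for code, lobe in sorted(volume.lobe_legend.items()):
        sel = volume.lobe_labels == code
        n_vox = int(sel.sum())
        if n_vox == 0:
            continue
        lobe_terms = np.flatnonzero(term_lobes == lobe)
        if lobe_terms.size == 0:
            raise ValueError(f"lobe {lobe} has no airway termination points")
        centers = volume.index_to_mm(np.argwhere(sel))
        _, nearest = cKDTree(term_pts[lobe_terms]).query(centers)
        assigned = term_ids[lobe_terms][nearest]
        obstructed = np.isin(assigned, list(plugged))
        v_o = float(obstructed.sum()) * voxel_vol
        v_t = n_vox * voxel_vol
        per_lobe[lobe] = {"V_o_mm3": v_o, "V_t_mm3": v_t, "OLVP_percent": 100.0 * v_o / v_t}
        total_vo += v_o
        total_vt += v_t
    return OlvpResult(per_lobe=per_lobe, whole_lung_olvp=100.0 * total_vo / total_vt)
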