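"""Airway-tree topology: branches, validation, plug-to-branch mapping.

The airway tree is a rooted tree of cylindrical branches. The trachea is
generation 0 and each bifurcation increments the generation. Every terminal
branch (no children) owns a *termination point*: the most distal centerline
point. Plugs are localized by a nearest-termination-point search in Euclidean
(mm) space, inheriting the generation and lobe of the owning terminal branch.

Generation groups used throughout the package: proximal (generation <= 7),
intermediate (8-9) and distal (>= 10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AirwayBranch",
    "AirwayTree",
    "PlugMap",
    "GENERATION_GROUPS",
    "generation_group",
    "validate_tree",
    "map_plugs",
    "generation_summary",
]

LOBES = ("RUL", "RML", "RLL", "LUL", "LLL")
GENERATION_GROUPS = ("proximal", "intermediate", "distal")


def generation_group(generation: int) -> str:
    """Proximal (<=7), intermediate (8-9) or distal (>=10) group of a generation."""
    if generation <= 7:
        return "proximal"
    if generation <= 9:
        return "intermediate"
    return "distal"


@dataclass
class AirwayBranch:
    """One airway segment between two bifurcations (or trachea / a terminal)."""

    branch_id: int
    parent_id: int | None
    centerline: np.ndarray  # (n_points, 3) mm, proximal -> distal
    radius: float  # mm, mean lumen radius of the segment
    generation: int
    lobe: str = "central"
    length: float | None = None  # mm; derived from the centerline when absent

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
            raise ValueError(f"branch {self.branch_id}: centerline needs >=2 xyz points")
        if self.length is None:
            self.length = float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    @property
    def start(self) -> np.ndarray:
        return self.centerline[0]

    @property
    def end(self) -> np.ndarray:
        return self.centerline[-1]


@dataclass
class AirwayTree:
    """Rooted airway tree with parent->children adjacency."""

    branches: dict[int, AirwayBranch]
    root_id: int

    _children: dict[int, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._children = {bid: [] for bid in self.branches}
        for b in self.branches.values():
            if b.parent_id is not None and b.parent_id in self._children:
                self._children[b.parent_id].append(b.branch_id)
        for kids in self._children.values():
            kids.sort()

    def children(self, branch_id: int) -> list[int]:
        return self._children[branch_id]

    def is_terminal(self, branch_id: int) -> bool:
        return not self._children[branch_id]

    @property
    def terminal_ids(self) -> list[int]:
        return sorted(b for b in self.branches if self.is_terminal(b))

    def termination_point(self, branch_id: int) -> np.ndarray:
        if not self.is_terminal(branch_id):
            raise ValueError(f"branch {branch_id} is not terminal")
        return self.branches[branch_id].end

    def termination_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(branch ids, (n,3) mm points) of all terminations, id-sorted."""
        ids = np.array(self.terminal_ids, dtype=int)
        pts = np.array([self.branches[i].end for i in ids], dtype=float).reshape(-1, 3)
        return ids, pts

    def subtree_ids(self, branch_id: int) -> list[int]:
        out, stack = [], [branch_id]
        while stack:
            b = stack.pop()
            out.append(b)
            stack.extend(self._children[b])
        return out

    def pruned(self, terminal_at: Iterable[int]) -> "AirwayTree":
        """Copy of the tree with each listed branch made terminal.

        All descendants of the listed branches are removed. This models the
        lumen an airway segmentation actually sees when a branch is fully
        occluded: the segmented tree terminates at the occlusion.
        """
        cut = set(terminal_at)
        drop: set[int] = set()
        for bid in cut:
            if bid not in self.branches:
                raise KeyError(f"unknown branch {bid}")
            for child in self._children[bid]:
                drop.update(self.subtree_ids(child))
        kept = {bid: b for bid, b in self.branches.items() if bid not in drop}
        return AirwayTree(branches=kept, root_id=self.root_id)

    # ------------------------------------------------------------------ IO
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "root": self.root_id,
            "branches": [
                {
                    "id": b.branch_id,
                    "parent": b.parent_id,
                    "centerline": b.centerline.tolist(),
                    "radius": b.radius,
                    "length": b.length,
                    "generation": b.generation,
                    "lobe": b.lobe,
                }
                for b in sorted(self.branches.values(), key=lambda x: x.branch_id)
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AirwayTree":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        branches = {
            int(rec["id"]): AirwayBranch(
                branch_id=int(rec["id"]),
                parent_id=None if rec["parent"] is None else int(rec["parent"]),
                centerline=np.asarray(rec["centerline"], dtype=float),
                radius=float(rec["radius"]),
                generation=int(rec["generation"]),
                lobe=rec.get("lobe", "central"),
                length=float(rec["length"]) if rec.get("length") is not None else None,
            )
            for rec in payload["branches"]
        }
        return cls(branches=branches, root_id=int(payload["root"]))


def validate_tree(tree: AirwayTree) -> list[str]:
    """Check structural invariants; return a list of violation messages."""
    v: list[str] = []
    if tree.root_id not in tree.branches:
        return [f"root {tree.root_id} missing from branches"]
    root = tree.branches[tree.root_id]
    if root.parent_id is not None:
        v.append("root has a parent")
    if root.generation != 0:
        v.append(f"root generation is {root.generation}, expected 0")
    g = nx.DiGraph()
    for b in tree.branches.values():
        if b.length is None or b.length <= 0:
            v.append(f"branch {b.branch_id}: non-positive length")
        if b.radius <= 0:
            v.append(f"branch {b.branch_id}: non-positive radius")
        if b.branch_id != tree.root_id:
            if b.parent_id is None:
                v.append(f"branch {b.branch_id}: missing parent")
            elif b.parent_id not in tree.branches:
                v.append(f"branch {b.branch_id}: unknown parent {b.parent_id}")
            else:
                g.add_edge(b.parent_id, b.branch_id)
                parent = tree.branches[b.parent_id]
                if b.generation != parent.generation + 1:
                    v.append(
                        f"branch {b.branch_id}: generation {b.generation} != "
                        f"parent generation {parent.generation} + 1"
                    )
    g.add_nodes_from(tree.branches)
    if not nx.is_directed_acyclic_graph(g):
        v.append("adjacency contains a cycle")
    elif g.number_of_nodes() and not nx.is_weakly_connected(g):
        v.append("tree is not connected")
    return v


@dataclass
class PlugMap:
    """Plug-to-branch assignments with generation/lobe/group tallies."""

    scan_id: str
    assignments: pd.DataFrame  # plug_id, branch_id, generation, lobe, distance_mm, group

    @property
    def plug_count(self) -> int:
        return len(self.assignments)

    @property
    def plugged_branch_ids(self) -> set[int]:
        return set(self.assignments["branch_id"].astype(int))

    @property
    def generation_counts(self) -> pd.Series:
        return self.assignments["generation"].value_counts().sort_index()

    @property
    def lobe_counts(self) -> pd.Series:
        return self.assignments["lobe"].value_counts().sort_index()

    @property
    def group_counts(self) -> dict[str, int]:
        counts = self.assignments["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GENERATION_GROUPS}

    def to_csv(self, path: str | Path) -> None:
        self.assignments.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, scan_id: str = "") -> "PlugMap":
        df = pd.read_csv(path)
        if "group" not in df.columns:
            df["group"] = df["generation"].map(generation_group)
        return cls(scan_id=scan_id, assignments=df)


def _plug_centroids(plugs) -> tuple[list, np.ndarray]:
    """Accept a morphometry table or objects with plug_id/centroid attributes."""
    if isinstance(plugs, pd.DataFrame):
        ids = list(plugs["plug_id"])
        pts = plugs[["centroid_x", "centroid_y", "centroid_z"]].to_numpy(dtype=float)
    else:
        ids = [p.plug_id for p in plugs]
        pts = np.array([np.asarray(p.centroid, dtype=float) for p in plugs]).reshape(-1, 3)
    return ids, pts


def map_plugs(tree: AirwayTree, plugs, scan_id: str = "") -> PlugMap:
    """Assign each plug to the nearest airway termination point (Euclidean).

    Generation and lobe are inherited from the terminal branch owning that
    termination point. Distance ties are broken toward the lowest branch id
    (termination points are scanned in ascending branch-id order).
    """
    term_ids, term_pts = tree.termination_points()
    if term_ids.size == 0:
        raise ValueError("tree has no termination points")
    ids, pts = _plug_centroids(plugs)
    rows = []
    for pid, p in zip(ids, pts):
        d = np.linalg.norm(term_pts - p, axis=1)
        j = int(np.argmin(d))  # first minimum -> lowest branch id
        bid = int(term_ids[j])
        b = tree.branches[bid]
        rows.append(
            {
                "plug_id": pid,
                "branch_id": bid,
                "generation": b.generation,
                "lobe": b.lobe,
                "distance_mm": float(d[j]),
                "group": generation_group(b.generation),
            }
        )
    cols = ["plug_id", "branch_id", "generation", "lobe", "distance_mm", "group"]
    return PlugMap(scan_id=scan_id, assignments=pd.DataFrame(rows, columns=cols))


def generation_summary(tree: AirwayTree, plug_map: PlugMap | None = None) -> pd.DataFrame:
    """Per-generation plug counts and mean airway diameter (2r over branches)."""
    gens = sorted({b.generation for b in tree.branches.values()})
    diam = {
        g: float(np.mean([2.0 * b.radius for b in tree.branches.values() if b.generation == g]))
        for g in gens
    }
    counts: Mapping[int, int] = {}
    if plug_map is not None:
        counts = plug_map.generation_counts.to_dict()
    return pd.DataFrame(
        {
            "generation": gens,
            "plug_count": [int(counts.get(g, 0)) for g in gens],
            "mean_diameter_mm": [diam[g] for g in gens],
        }
    )
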