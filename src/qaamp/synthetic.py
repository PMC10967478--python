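"""Synthetic airway/lung phantoms with ground-truth mucus plugs.

Every downstream stage of the pipeline (adjudication, segmentation,
morphometry, mapping, resistance/obstruction scoring, longitudinal tracking)
is exercised on phantoms produced here, because the real CT scans the method
targets are controlled-access. Four generators are provided:

* :func:`generate_airway_tree` — a strictly bifurcating 3-D airway tree with
  per-generation length/radius tapering (the default radius ratio
  ``2**(-1/3)`` keeps total cross-section roughly area-preserving, the
  classic symmetric-lung scaling).
* :func:`rasterize_phantom` — a CT-like HU volume on a regular grid with
  lumen / parenchyma / plug contrast, Gaussian noise, per-voxel lobe labels,
  and exact per-plug ground-truth voxel masks.
* :func:`simulate_annotations` — slice-wise elliptical reader annotations
  over the truth masks, with configurable misses, slice skips and ellipse
  dilation noise to emulate reader disagreement.
* :func:`simulate_followup` — a paired "year-3" plug set with known
  persistent/transient labels and zero-mean size jitter.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .annotations import AnnotationSet, EllipseAnnotation
from .segmentation import PlugMask
from .tree import LOBES, AirwayBranch, AirwayTree
from .volume import CTVolume

__all__ = [
    "TreeConfig",
    "PhantomSpec",
    "ReaderModel",
    "FollowupConfig",
    "Phantom",
    "generate_airway_tree",
    "rasterize_phantom",
    "simulate_annotations",
    "simulate_followup",
]


# --------------------------------------------------------------------------- configs
@dataclass
class TreeConfig:
    """Geometry of a strictly bifurcating airway-tree phantom.

    Defaults approximate adult airway anatomy: an 18 mm diameter, 100 mm
    trachea tapering by ``2**(-1/3)`` per generation puts generations 6-9 at
    2-4.5 mm diameter, the calibre range where mucus plugs concentrate.
    """

    seed: int = 0
    max_generation: int = 8
    root_length: float = 100.0  # mm
    root_radius: float = 9.0  # mm
    length_ratio: float = 0.8  # per generation
    radius_ratio: float = 2.0 ** (-1.0 / 3.0)  # per generation
    branch_angle: float = 35.0  # degrees off the parent direction
    jitter_sd: float = 0.0  # fractional jitter on lengths/radii/angles
    min_radius: float = 0.2  # mm
    lobe_count: int = 5

    def validate(self) -> None:
        if not (0 < self.length_ratio <= 1 and 0 < self.radius_ratio <= 1):
            raise ValueError("length_ratio and radius_ratio must lie in (0, 1]")
        if self.max_generation < 1:
            raise ValueError("max_generation must be >= 1")
        if self.min_radius <= 0:
            raise ValueError("min_radius must be positive")
        if not (1 <= self.lobe_count <= len(LOBES)):
            raise ValueError(f"lobe_count must be in 1..{len(LOBES)}")


@dataclass
class PhantomSpec:
    """HU contrast, grid geometry and plug placements for rasterization.

    ``plug_placements`` is a list of ``(branch_id, fractional_start,
    length_mm)``: a fully occluding plug cylinder coaxial with the branch,
    starting at the given fraction of the branch length.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.5)  # mm; axial in-plane, then slice
    parenchyma_hu: tuple[float, float] = (-870.0, 40.0)  # mean, noise sd
    lumen_hu: float = -1000.0
    plug_hu: tuple[float, float] = (-150.0, 30.0)  # mean, noise sd
    plug_placements: list[tuple[int, float, float]] = field(default_factory=list)

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not (self.lumen_hu < self.parenchyma_hu[0] < self.plug_hu[0]):
            raise ValueError("HU ordering must be lumen < parenchyma < plug")


@dataclass
class ReaderModel:
    """Stochastic reader behavior for simulated slice-wise annotations."""

    miss_probability: float = 0.1  # per plug
    slice_skip_probability: float = 0.05
    ellipse_dilation_sd: float = 0.5  # voxels, on each full axis extent
    seed: int = 0

    def validate(self) -> None:
        for p in (self.miss_probability, self.slice_skip_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class FollowupConfig:
    """Longitudinal behavior of plugs between baseline and a year-3 visit.

    The default persistence probability follows the observed fraction of
    baseline plugs still occupying the same airway three years later (47%);
    size jitter is zero-mean, matching change distributions centered on zero.
    """

    persistence_probability: float = 0.47
    length_jitter_sd: float = 3.0  # mm
    volume_jitter_sd: float = 50.0  # mm^3 (used for table-level simulation)
    new_plug_rate: float = 5.0  # expected count of newly formed plugs
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.persistence_probability <= 1:
            raise ValueError("persistence_probability must lie in [0, 1]")


# --------------------------------------------------------------------------- tree
def _perpendicular(d: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    return u / np.linalg.norm(u)


def generate_airway_tree(config: TreeConfig) -> AirwayTree:
    """Grow a strictly bifurcating, 3-D embedded airway tree.

    Branch ids are breadth-first (root 0). Child directions make the
    configured branch angle with the parent, in a bifurcation plane that
    rotates by a golden-angle increment per branch so successive generations
    spread in 3-D; ``jitter_sd`` adds seeded multiplicative Gaussian jitter
    to lengths, radii and angles. Lobes are assigned to contiguous groups of
    generation-3 subtrees (generations below that are "central").
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    golden = math.pi * (3.0 - math.sqrt(5.0))

    def jit() -> float:
        return float(1.0 + config.jitter_sd * rng.standard_normal()) if config.jitter_sd else 1.0

    branches: dict[int, AirwayBranch] = {}
    root_dir = np.array([0.0, 0.0, 1.0])
    root_end = np.zeros(3) + root_dir * config.root_length
    branches[0] = AirwayBranch(
        branch_id=0, parent_id=None, centerline=np.array([np.zeros(3), root_end]),
        radius=config.root_radius, generation=0,
    )
    directions = {0: root_dir}
    next_id = 1
    frontier = [0]
    for gen in range(1, config.max_generation + 1):
        new_frontier = []
        for parent in frontier:
            pb = branches[parent]
            d = directions[parent]
            u = _perpendicular(d)
            v = np.cross(d, u)
            phi = golden * parent + (rng.uniform(0, 2 * math.pi) if config.jitter_sd else 0.0)
            w = math.cos(phi) * u + math.sin(phi) * v
            for sign in (1.0, -1.0):
                theta = math.radians(config.branch_angle) * jit()
                cd = math.cos(theta) * d + sign * math.sin(theta) * w
                cd /= np.linalg.norm(cd)
                length = config.root_length * config.length_ratio**gen * jit()
                radius = max(
                    config.root_radius * config.radius_ratio**gen * jit(), config.min_radius
                )
                start = pb.end
                end = start + cd * length
                branches[next_id] = AirwayBranch(
                    branch_id=next_id, parent_id=parent,
                    centerline=np.array([start, end]), radius=radius, generation=gen,
                )
                directions[next_id] = cd
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    if not branches:
        raise ValueError("configuration produced no branches")

    tree = AirwayTree(branches=branches, root_id=0)
    _assign_lobes(tree, config.lobe_count)
    return tree


def _assign_lobes(tree: AirwayTree, lobe_count: int) -> None:
    """Assign lobes to contiguous groups of subtree roots.

    Roots are the branches at the shallowest generation holding at least
    ``lobe_count`` branches (generation 3 for the five classic lobes,
    generation 2 for four); splitting them into contiguous groups assigns
    every deeper branch the lobe of its subtree. Shallower generations stay
    "central". Trees shallower than the needed depth fall back to their
    deepest generation.
    """
    max_gen = max(b.generation for b in tree.branches.values())
    depth = min(max(1, math.ceil(math.log2(max(lobe_count, 2)))), max_gen)
    roots = sorted(b.branch_id for b in tree.branches.values() if b.generation == depth)
    if not roots:
        return
    groups = np.array_split(np.array(roots), min(lobe_count, len(roots)))
    for lobe, grp in zip(LOBES, groups):
        for rid in grp:
            for bid in tree.subtree_ids(int(rid)):
                tree.branches[bid].lobe = lobe


# --------------------------------------------------------------------------- phantom
@dataclass
class Phantom:
    """Rasterized phantom: volume, truth masks, truth table, observed tree."""

    volume: CTVolume
    plug_masks: dict[int, PlugMask]
    truth: pd.DataFrame  # plug_id, branch_id, start_frac, length_mm, generation, lobe
    tree: AirwayTree  # the full generating tree
    observed_tree: AirwayTree  # pruned distal to plugs (what segmentation would see)


def _cylinder_mask(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    origin: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
    caps: bool = False,
) -> np.ndarray | None:
    """Boolean mask of voxel centers within ``radius`` of segment p0-p1.

    With ``caps`` the ends are hemispherical (a capsule — used for lumens so
    consecutive branches join smoothly); without, the cylinder is flat-ended
    so its voxel volume tracks the analytic ``pi * r**2 * L``. Returns
    ``None`` when the bounding box misses the grid; only the bounding
    subgrid is evaluated.
    """
    lo_mm = np.minimum(p0, p1) - radius
    hi_mm = np.maximum(p0, p1) + radius
    lo = np.floor((lo_mm - origin) / spacing).astype(int)
    hi = np.ceil((hi_mm - origin) / spacing).astype(int) + 1
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, shape)
    if np.any(lo_c >= hi_c):
        return None
    ax = [origin[i] + np.arange(lo_c[i], hi_c[i]) * spacing[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    d = p1 - p0
    seg_len2 = float(d @ d)
    rel = pts - p0
    t_raw = (rel @ d) / seg_len2 if seg_len2 > 0 else np.zeros(pts.shape[:3])
    t = np.clip(t_raw, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    sub = dist2 <= radius**2
    if not caps:
        sub &= (t_raw >= 0.0) & (t_raw <= 1.0)
    mask = np.zeros(shape, dtype=bool)
    mask[lo_c[0]: hi_c[0], lo_c[1]: hi_c[1], lo_c[2]: hi_c[2]] = sub
    return mask


def rasterize_phantom(tree: AirwayTree, spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Rasterize a tree into a CT-like HU volume with ground-truth plugs.

    The tree is centered in the grid. Parenchyma fills the background
    (mean + Gaussian noise), branch lumens are carved at ``lumen_hu``, and
    each plug placement overwrites its lumen stretch with ``plug_hu`` +
    noise, fully occluding the branch. Per-voxel lobe labels follow the
    nearest termination point of the full tree. The returned observed tree
    is pruned distal to every plugged branch.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)

    pts = np.concatenate([b.centerline for b in tree.branches.values()])
    pad = max(b.radius for b in tree.branches.values()) + 2.0
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    extent = np.asarray(shape) * spacing
    origin = (lo + hi) / 2.0 - extent / 2.0 + spacing / 2.0

    mean_par, sd_par = spec.parenchyma_hu
    data = np.full(shape, mean_par, dtype=np.float32)
    if sd_par:
        data += (sd_par * rng.standard_normal(shape)).astype(np.float32)

    lumen = np.zeros(shape, dtype=bool)
    for b in tree.branches.values():
        m = _cylinder_mask(shape, spacing, origin, b.start, b.end, b.radius, caps=True)
        if m is not None:
            lumen |= m
    data[lumen] = spec.lumen_hu

    mean_plug, sd_plug = spec.plug_hu
    plug_masks: dict[int, PlugMask] = {}
    rows = []
    plugged_branches = []
    for plug_id, (branch_id, start_frac, length_mm) in enumerate(spec.plug_placements):
        if branch_id not in tree.branches:
            raise KeyError(f"plug placement references unknown branch {branch_id}")
        b = tree.branches[branch_id]
        axis = (b.end - b.start) / np.linalg.norm(b.end - b.start)
        p0 = b.start + axis * (start_frac * b.length)
        p1 = p0 + axis * length_mm
        for p in (p0, p1):
            idx = (p - origin) / spacing
            if np.any(idx < -0.5) or np.any(idx > np.asarray(shape) - 0.5):
                raise ValueError(f"plug on branch {branch_id} falls outside the grid")
        m = _cylinder_mask(shape, spacing, origin, p0, p1, b.radius)
        if m is None or not m.any():
            raise ValueError(f"plug on branch {branch_id} rasterized to zero voxels")
        vox = np.argwhere(m)
        data[m] = mean_plug + (
            sd_plug * rng.standard_normal(len(vox)) if sd_plug else 0.0
        )
        plug_masks[plug_id] = PlugMask(
            plug_id=plug_id, indices=vox, spacing=spacing.copy(), origin=origin.copy()
        )
        plugged_branches.append(branch_id)
        rows.append(
            {
                "plug_id": plug_id,
                "branch_id": branch_id,
                "start_frac": start_frac,
                "length_mm": length_mm,
                "generation": b.generation,
                "lobe": b.lobe,
            }
        )

    term_ids, term_pts = tree.termination_points()
    lobe_names = sorted({tree.branches[int(i)].lobe for i in term_ids})
    legend = {code: name for code, name in enumerate(lobe_names, start=1)}
    name_to_code = {v: k for k, v in legend.items()}
    grid_idx = np.indices(shape).reshape(3, -1).T
    centers = origin + grid_idx * spacing
    _, nearest = cKDTree(term_pts).query(centers)
    term_lobe_codes = np.array(
        [name_to_code[tree.branches[int(i)].lobe] for i in term_ids], dtype=np.int16
    )
    lobe_labels = term_lobe_codes[nearest].reshape(shape)

    volume = CTVolume(
        data=data, spacing=spacing, origin=origin, lobe_labels=lobe_labels, lobe_legend=legend
    )
    truth_cols = ["plug_id", "branch_id", "start_frac", "length_mm", "generation", "lobe"]
    truth = pd.DataFrame(rows, columns=truth_cols)
    observed = tree.pruned(plugged_branches) if plugged_branches else tree
    return Phantom(
        volume=volume, plug_masks=plug_masks, truth=truth, tree=tree, observed_tree=observed
    )


# --------------------------------------------------------------------------- readers
def _slice_ellipse(vox_xy: np.ndarray) -> tuple[float, float, float, float]:
    """Tight axis-aligned ellipse (center, full extents) enclosing pixel centers.

    The aspect ratio follows the bounding box; the size is the smallest that
    puts every pixel center inside the inclusive ellipse, plus a half-voxel
    margin so the pixel footprint is covered too.
    """
    lo = vox_xy.min(axis=0)
    hi = vox_xy.max(axis=0)
    cx, cy = (lo + hi) / 2.0
    bw = hi[0] - lo[0] + 1.0
    bh = hi[1] - lo[1] + 1.0
    k = bw / bh
    dx = vox_xy[:, 0] - cx
    dy = vox_xy[:, 1] - cy
    a = float(np.sqrt(np.max(dx**2 + (k * dy) ** 2))) + 0.5
    b = a / k
    return float(cx), float(cy), 2.0 * a, 2.0 * b


def simulate_annotations(
    plug_masks: dict[int, PlugMask],
    reader: ReaderModel,
    scan_id: str = "phantom",
    reader_id: str = "reader",
) -> AnnotationSet:
    """Emulate one reader pass: an ellipse per plug per intersected slice.

    Whole plugs are missed with ``miss_probability``; retained plugs lose
    individual slices with ``slice_skip_probability`` (never all slices);
    ellipse extents receive additive Gaussian dilation noise.
    """
    reader.validate()
    rng = np.random.default_rng(reader.seed)
    annotations: list[EllipseAnnotation] = []
    for plug_id in sorted(plug_masks):
        mask = plug_masks[plug_id]
        if rng.random() < reader.miss_probability:
            continue
        slices = np.unique(mask.indices[:, 2])
        keep = rng.random(len(slices)) >= reader.slice_skip_probability
        if not keep.any():
            keep[rng.integers(len(slices))] = True
        for z in slices[keep]:
            xy = mask.indices[mask.indices[:, 2] == z][:, :2]
            cx, cy, w, h = _slice_ellipse(xy)
            if reader.ellipse_dilation_sd:
                # noise never shrinks the mark below a voxel-scale floor
                w = max(w + reader.ellipse_dilation_sd * rng.standard_normal(), 0.6 * w, 1.5)
                h = max(h + reader.ellipse_dilation_sd * rng.standard_normal(), 0.6 * h, 1.5)
            annotations.append(
                EllipseAnnotation(
                    scan_id=scan_id, reader_id=reader_id, plug_label=int(plug_id),
                    slice_index=int(z), center_x=cx, center_y=cy, width=w, height=h,
                )
            )
    return AnnotationSet(scan_id=scan_id, annotations=annotations)


# --------------------------------------------------------------------------- follow-up
def simulate_followup(
    baseline: pd.DataFrame, tree: AirwayTree, config: FollowupConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve a baseline truth table to a year-3 table with known labels.

    Each baseline plug survives on its branch with ``persistence_probability``
    (length jittered by a zero-mean Gaussian), otherwise disappears. New
    plugs appear on a Poisson(``new_plug_rate``) sample of unplugged terminal
    branches, with lengths drawn around the baseline mean. Returns the
    year-3 truth table (same schema as the baseline) and a label table
    ``(plug_id, label)`` with label in {persistent, transient}.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    followup_rows = []
    labels = []
    next_id = (int(baseline["plug_id"].max()) + 1) if len(baseline) else 0
    mean_len = float(baseline["length_mm"].mean()) if len(baseline) else 10.0

    for _, row in baseline.iterrows():
        persists = rng.random() < config.persistence_probability
        labels.append(
            {"plug_id": int(row["plug_id"]), "label": "persistent" if persists else "transient"}
        )
        if persists:
            new_len = row["length_mm"] + config.length_jitter_sd * rng.standard_normal()
            new_len = max(new_len, 1.0)
            out = row.to_dict()
            out["length_mm"] = float(new_len)
            followup_rows.append(out)

    occupied = set(baseline["branch_id"].astype(int))
    free = [b for b in tree.terminal_ids if b not in occupied]
    n_new = int(rng.poisson(config.new_plug_rate)) if config.new_plug_rate > 0 else 0
    for bid in rng.choice(free, size=min(n_new, len(free)), replace=False) if free else []:
        b = tree.branches[int(bid)]
        length = max(abs(mean_len + config.length_jitter_sd * rng.standard_normal()), 1.0)
        length = min(length, 0.9 * b.length)
        followup_rows.append(
            {
                "plug_id": next_id,
                "branch_id": int(bid),
                "start_frac": 0.05,
                "length_mm": float(length),
                "generation": b.generation,
                "lobe": b.lobe,
            }
        )
        next_id += 1

    cols = ["plug_id", "branch_id", "start_frac", "length_mm", "generation", "lobe"]
    followup = pd.DataFrame(followup_rows, columns=cols)
    label_df = pd.DataFrame(labels, columns=["plug_id", "label"])
    return followup, label_df


# --------------------------------------------------------------------------- config IO
def config_from_json(cls, source: str | Path):
    """Instantiate a config dataclass from a JSON file or JSON text."""
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        payload = json.loads(Path(source).read_text())
    else:
        payload = json.loads(str(source))
    if "plug_placements" in payload:
        payload["plug_placements"] = [tuple(p) for p in payload["plug_placements"]]
    if "grid_shape" in payload:
        payload["grid_shape"] = tuple(payload["grid_shape"])
    if "spacing" in payload and isinstance(payload["spacing"], list):
        payload["spacing"] = tuple(payload["spacing"])
    for key in ("parenchyma_hu", "plug_hu"):
        if key in payload and isinstance(payload[key], list):
            payload[key] = tuple(payload[key])
    return cls(**payload)


def config_to_json(config, path: str | Path | None = None) -> str:
    text = json.dumps(asdict(config), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
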