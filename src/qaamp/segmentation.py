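"""Plug segmentation: elliptical ROI extraction + Gustafson-Kessel clustering.

The voxels inside a plug's stacked elliptical annotations form a volumetric
subset containing plug material, airway lumen and some parenchyma. A
two-cluster Gustafson-Kessel (GK) fuzzy clustering on the scalar HU values
separates radiodense plug from the darker background; the cluster with the
higher centroid is the foreground, and the single largest 26-connected
foreground component is the plug.

GK clustering generalizes fuzzy c-means by giving each cluster its own
Mahalanobis-like metric derived from its fuzzy covariance under a
unit-volume (determinant) constraint. On 1-D features the determinant
normalization cancels the variance, so the induced metric is Euclidean;
the per-cluster variances are still estimated (with a floor) and reported.
The result is therefore invariant to affine rescaling of the intensities,
which makes the segmentation HU-calibration-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label

from .volume import CTVolume

__all__ = [
    "GKConfig",
    "GKResult",
    "RoiSubset",
    "PlugMask",
    "DegenerateInputError",
    "extract_roi_volume",
    "gk_cluster",
    "segment_plug",
]


class DegenerateInputError(ValueError):
    """Raised when clustering input cannot support two clusters."""


@dataclass
class GKConfig:
    """Hyperparameters for two-cluster GK fuzzy clustering on HU values."""

    cluster_count: int = 2
    fuzzifier: float = 2.0  # m > 1
    tolerance: float = 1e-5  # max membership change between iterations
    max_iterations: int = 100
    covariance_floor: float = 1e-6  # times the data variance
    seed: int = 0

    def validate(self) -> None:
        if self.cluster_count != 2:
            raise ValueError("the plug/background model uses exactly 2 clusters")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must exceed 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class RoiSubset:
    """Voxels of one plug's stacked elliptical ROIs, with intensities."""

    plug_id: int
    indices: np.ndarray  # (n, 3) integer voxel indices
    intensities: np.ndarray  # (n,) HU
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if len(self.indices) == 0:
            raise ValueError(f"plug {self.plug_id}: empty ROI subset")
        if len(self.indices) != len(self.intensities):
            raise ValueError("indices and intensities disagree in length")

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.indices.min(axis=0), self.indices.max(axis=0)


@dataclass
class PlugMask:
    """A segmented plug: one 26-connected set of voxel indices."""

    plug_id: int
    indices: np.ndarray  # (n, 3) integer voxel indices
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).reshape(-1, 3)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if len(self.indices) == 0:
            raise ValueError(f"plug {self.plug_id}: empty mask")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def coordinates_mm(self) -> np.ndarray:
        """Physical coordinates of voxel centers."""
        return self.origin + self.indices * self.spacing

    def to_array(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[tuple(self.indices.T)] = True
        return out


@dataclass
class GKResult:
    memberships: np.ndarray  # (n, 2), columns ordered by ascending centroid
    centroids: np.ndarray  # (2,), ascending
    variances: np.ndarray  # (2,), floored fuzzy variances
    objective_history: list[float]
    n_iterations: int
    converged: bool


# --------------------------------------------------------------------------- ROI
def extract_roi_volume(volume: CTVolume, plug_annotations) -> RoiSubset:
    """Union of per-slice elliptical ROI voxels for one plug.

    A voxel (x, y) on slice z is included iff its center satisfies the
    inclusive ellipse inequality of that slice's annotation. Ellipses fully
    outside the grid raise.
    """
    anns = sorted(plug_annotations, key=lambda a: a.slice_index)
    if not anns:
        raise ValueError("no annotations supplied")
    nx, ny, nz = volume.shape
    picked: list[np.ndarray] = []
    for a in anns:
        if not (0 <= a.slice_index < nz):
            raise ValueError(f"plug {a.plug_label}: slice {a.slice_index} outside volume")
        x0 = max(int(np.floor(a.center_x - a.width / 2.0)), 0)
        x1 = min(int(np.ceil(a.center_x + a.width / 2.0)), nx - 1)
        y0 = max(int(np.floor(a.center_y - a.height / 2.0)), 0)
        y1 = min(int(np.ceil(a.center_y + a.height / 2.0)), ny - 1)
        if x0 > x1 or y0 > y1:
            raise ValueError(
                f"plug {a.plug_label} slice {a.slice_index}: ellipse outside the grid"
            )
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1), indexing="ij")
        inside = a.contains(xs, ys)
        if not inside.any():
            raise ValueError(
                f"plug {a.plug_label} slice {a.slice_index}: ellipse contains no voxels"
            )
        z = np.full(inside.sum(), a.slice_index, dtype=int)
        picked.append(np.column_stack([xs[inside], ys[inside], z]))
    indices = np.unique(np.concatenate(picked), axis=0)
    intensities = volume.data[tuple(indices.T)].astype(float)
    return RoiSubset(
        plug_id=int(anns[0].plug_label), indices=indices, intensities=intensities,
        spacing=volume.spacing.copy(), origin=volume.origin.copy(),
    )


# --------------------------------------------------------------------------- GK
def gk_cluster(intensities: np.ndarray, config: GKConfig | None = None) -> GKResult:
    """Two-cluster GK fuzzy clustering of scalar intensities.

    Centroids are initialized at the 10th/90th intensity percentiles
    (seeded random restart only if those coincide). Iteration alternates
    membership and centroid/variance updates until the maximum membership
    change falls below tolerance. Memberships sum to one per voxel;
    centroids are returned in ascending order with matching columns.
    """
    config = config or GKConfig()
    config.validate()
    x = np.asarray(intensities, dtype=float).reshape(-1)
    if len(np.unique(x)) < 2:
        raise DegenerateInputError("all intensities identical; cannot form two clusters")
    data_var = float(np.var(x))
    floor = config.covariance_floor * data_var
    m = config.fuzzifier

    v = np.percentile(x, [10.0, 90.0]).astype(float)
    if v[0] == v[1]:
        rng = np.random.default_rng(config.seed)
        v = rng.choice(np.unique(x), size=2, replace=False).astype(float)
        v.sort()

    u = np.zeros((len(x), 2))
    variances = np.full(2, max(data_var, floor))
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        # GK distance with unit-volume metric; in 1-D the determinant
        # normalization cancels the variance and d^2 is Euclidean.
        d2 = (x[:, None] - v[None, :]) ** 2
        u_new = _memberships(d2, m)
        um = u_new**m
        weights = um.sum(axis=0)
        v = (um * x[:, None]).sum(axis=0) / weights
        variances = np.maximum((um * (x[:, None] - v[None, :]) ** 2).sum(axis=0) / weights, floor)
        d2 = (x[:, None] - v[None, :]) ** 2
        history.append(float((u_new**m * d2).sum()))
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < config.tolerance:
            converged = True
            break

    order = np.argsort(v)
    return GKResult(
        memberships=u[:, order],
        centroids=v[order],
        variances=variances[order],
        objective_history=history,
        n_iterations=it,
        converged=converged,
    )


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Standard fuzzy membership update; exact points get crisp membership."""
    zero = d2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    rows = zero.any(axis=1)
    if rows.any():
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return u


def segment_plug(
    subset: RoiSubset, config: GKConfig | None = None, return_qc: bool = False
):
    """Segment one plug from its ROI subset.

    Voxels are assigned to the higher-centroid (foreground) cluster by
    maximum membership, ties favoring the foreground; the largest
    26-connected foreground component becomes the plug mask.
    """
    result = gk_cluster(subset.intensities, config)
    foreground = result.memberships[:, 1] >= result.memberships[:, 0]
    if not foreground.any():
        raise ValueError(f"plug {subset.plug_id}: empty foreground after clustering")

    lo, hi = subset.bounding_box
    shape = tuple(hi - lo + 1)
    grid = np.zeros(shape, dtype=bool)
    local = subset.indices - lo
    grid[tuple(local[foreground].T)] = True
    labels = cc_label(grid, connectivity=3)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts.argmax()
    component = np.argwhere(labels == keep) + lo
    mask = PlugMask(
        plug_id=subset.plug_id, indices=component,
        spacing=subset.spacing.copy(), origin=subset.origin.copy(),
    )
    if return_qc:
        qc = {
            "plug_id": subset.plug_id,
            "n_roi_voxels": int(len(subset.indices)),
            "n_mask_voxels": int(len(mask)),
            "centroids_hu": [float(c) for c in result.centroids],
            "n_iterations": result.n_iterations,
            "converged": result.converged,
        }
        return mask, qc
    return mask


def save_masks(
    masks: dict[int, PlugMask], shape: tuple[int, int, int], volume: CTVolume, path: str | Path
) -> None:
    """Write all masks as one integer-labeled NIfTI raster (label = plug id + 1)."""
    labeled = np.zeros(shape, dtype=np.int16)
    for pid in sorted(masks):
        labeled[tuple(masks[pid].indices.T)] = pid + 1
    CTVolume(
        data=labeled.astype(np.float32), spacing=volume.spacing, origin=volume.origin
    ).save(path)
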