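"""CT-like volume container with physical spacing and per-voxel lobe labels.

The array is indexed ``(x, y, z)`` with axis 2 the axial (slice) direction,
matching the slice-wise annotation convention used throughout the package.
Intensities are in Hounsfield units (HU). Voxel ``(i, j, k)`` has its center
at ``origin + index * spacing`` (mm); all geometry downstream (morphometry,
airway mapping, obstruction scoring) works in this physical frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """A 3-D HU raster with spacing, origin and optional lobe-label map."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lobe_labels: np.ndarray | None = None
    lobe_legend: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive mm values")
        if self.lobe_labels is not None:
            self.lobe_labels = np.asarray(self.lobe_labels, dtype=np.int16)
            if self.lobe_labels.shape != self.data.shape:
                raise ValueError("lobe label map must match volume shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical (mm) coordinates of voxel centers for integer indices."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def lobe_name(self, code: int) -> str:
        if self.lobe_legend is None:
            raise ValueError("volume carries no lobe legend")
        return self.lobe_legend[int(code)]

    # ------------------------------------------------------------------ IO
    def _affine(self) -> np.ndarray:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        return affine

    def save(self, path: str | Path) -> None:
        """Write volume (and lobe map, if any) as NIfTI next to ``path``.

        ``path`` names the HU volume; lobe labels go to ``<stem>_lobes.nii``
        with the legend in ``<stem>_lobes.json``.
        """
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data, self._affine()), str(path))
        if self.lobe_labels is not None:
            stem = path.name.removesuffix(".gz").removesuffix(".nii")
            lobe_path = path.with_name(stem + "_lobes.nii")
            nib.save(nib.Nifti1Image(self.lobe_labels, self._affine()), str(lobe_path))
            legend = {str(k): v for k, v in (self.lobe_legend or {}).items()}
            lobe_path.with_suffix(".json").write_text(json.dumps(legend, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CTVolume":
        path = Path(path)
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3]
        data = np.asarray(img.dataobj, dtype=np.float32)
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        lobe_path = path.with_name(stem + "_lobes.nii")
        lobes = legend = None
        if lobe_path.exists():
            lobes = np.asarray(nib.load(str(lobe_path)).dataobj, dtype=np.int16)
            legend_path = lobe_path.with_suffix(".json")
            if legend_path.exists():
                legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
        return cls(data=data, spacing=spacing, origin=origin, lobe_labels=lobes, lobe_legend=legend)
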