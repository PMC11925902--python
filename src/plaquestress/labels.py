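"""Voxel label conventions and the :class:`LabelVolume` container.

A label volume is the in-memory form of a segmented CTA acquisition: an
isotropic voxel grid in which each voxel carries exactly one tissue label.
Pre-reconstruction volumes contain only what a CTA segmentation can see
(lumen, calcific and lipid plaque components); the wall-reconstruction step
adds the fibrous plaque content and the healthy wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np


class Label(IntEnum):
    """Tissue labels. Values are stable and used on disk."""

    BACKGROUND = 0
    LUMEN = 1
    CALCIFIC = 2
    LIPID = 3
    FIBROUS = 4
    HEALTHY_WALL = 5


#: The three plaque components that enter volume and stress indexes.
PLAQUE_LABELS = (Label.CALCIFIC, Label.LIPID, Label.FIBROUS)

#: Every solid (non-lumen, non-background) label of a reconstructed wall.
WALL_LABELS = (Label.CALCIFIC, Label.LIPID, Label.FIBROUS, Label.HEALTHY_WALL)

COMPONENT_NAMES = {
    Label.CALCIFIC: "calcific",
    Label.LIPID: "lipid",
    Label.FIBROUS: "fibrous",
    Label.HEALTHY_WALL: "healthy_wall",
}


@dataclass
class LabelVolume:
    """Isotropic voxel grid of mutually exclusive tissue labels.

    Parameters
    ----------
    data
        ``(nx, ny, nz)`` array of ``Label`` values (stored as uint8).
    voxel_size
        Isotropic voxel edge length in mm.
    origin
        World coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 3:
            raise ValueError("label data must be a 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive (mm)")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.voxel_size) ** 3

    def count(self, label: Label) -> int:
        return int(np.count_nonzero(self.data == int(label)))

    def mask(self, *labels: Label) -> np.ndarray:
        out = np.zeros(self.data.shape, dtype=bool)
        for lab in labels:
            out |= self.data == int(lab)
        return out

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of the centres of the masked voxels."""
        idx = np.argwhere(mask)
        return idx * self.voxel_size + self.origin

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.voxel_size, self.origin.copy())

    # -- I/O -----------------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data, affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        affine = img.affine
        scales = np.linalg.norm(affine[:3, :3], axis=0)
        if not np.allclose(scales, scales[0], rtol=1e-3):
            raise ValueError("anisotropic voxels are not supported")
        data = np.asarray(img.dataobj).astype(np.uint8)
        return cls(data, float(scales[0]), affine[:3, 3].copy())
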