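"""Lightweight volumetric image container with NIfTI round-tripping.

All pipeline stages operate on a single common space: every image in a study
shares one grid shape and one isotropic voxel size. The container deliberately
carries only what the statistics need (data + voxel size); full affine
bookkeeping is delegated to nibabel at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class VolumeImage:
    """A 3D scalar or integer-label volume on an isotropic grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values. Integer dtype for label volumes (atlas, lesion masks),
        float for continuous maps (abnormality, r/p/t/z maps).
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    """

    data: np.ndarray
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def volume_mm3(self) -> float:
        """Total volume of nonzero voxels (mm^3)."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume_mm3

    def same_grid(self, other: "VolumeImage") -> bool:
        return self.shape == other.shape and np.isclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj), float(zooms[0]))


def check_same_grid(*images: VolumeImage) -> None:
    first = images[0]
    for img in images[1:]:
        if not first.same_grid(img):
            raise ValueError(
                f"images on mismatched grids: {first.shape}@{first.voxel_size_mm}mm "
                f"vs {img.shape}@{img.voxel_size_mm}mm"
            )
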