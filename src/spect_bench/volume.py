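"""Volumes and attenuation maps: the universal 3D image currency.

Array axes are ``(x, y, z)`` with ``z`` the rotation / long axis.  All
short-axis-aligned volumes place the LV apex toward ``-z``.  Volumes are
stored as float64 (counts, activity, reconstructions) together with their
isotropic voxel size in mm and an orientation tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Volume", "AttenuationMap", "load_volume", "save_volume"]


@dataclass
class Volume:
    """A 3D scalar field on an isotropic grid.

    Parameters
    ----------
    data:
        3D array, axes ``(x, y, z)``.
    voxel_mm:
        Isotropic voxel edge length in mm.
    orientation:
        ``"short-axis"`` (default) or ``"scanner"``; bookkeeping only.
    """

    data: np.ndarray
    voxel_mm: float = 4.8
    orientation: str = "short-axis"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_mm, self.orientation)

    def like(self, data: np.ndarray) -> "Volume":
        """A new volume on this grid holding ``data``."""
        return Volume(np.asarray(data, dtype=np.float64), self.voxel_mm, self.orientation)

    def total(self) -> float:
        return float(self.data.sum())


@dataclass
class AttenuationMap:
    """Linear attenuation coefficients (1/cm at 140 keV) on a volume grid."""

    mu: Volume

    def __post_init__(self) -> None:
        if np.any(self.mu.data < 0):
            raise ValueError("attenuation coefficients must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mu.shape


def save_volume(vol: Volume, path: str) -> None:
    """Write a volume as NIfTI with the voxel size in the affine."""
    affine = np.diag([vol.voxel_mm, vol.voxel_mm, vol.voxel_mm, 1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms((vol.voxel_mm,) * 3)
    nib.save(img, path)


def load_volume(path: str, orientation: str = "short-axis") -> Volume:
    """Read a NIfTI volume; voxel size is taken from the header zooms."""
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return Volume(data, float(zooms[0]), orientation)
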