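"""Volumetric image containers and NIfTI I/O.

``VolumeImage`` is the unit of all imaging operations in this package: a 3D
scalar field plus voxel spacing and an affine placing it in world space.
``BrainMask`` is a boolean field on the same grid. Both round-trip through
NIfTI via nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class VolumeImage:
    """A 3D scalar image with geometry metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; must be finite.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world transform. Defaults to a diagonal affine built from
        ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voxel values must all be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "VolumeImage":
        """New image with the same geometry but different voxel values."""
        return VolumeImage(data=data, spacing=self.spacing, affine=self.affine.copy())


@dataclass
class BrainMask:
    """Boolean foreground mask on the same grid as its image."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask is empty")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def save_nifti(img: VolumeImage | BrainMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = img.data.astype(np.uint8) if isinstance(img, BrainMask) else img.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, img.affine), str(path))
    return path


def load_nifti(path: str | Path) -> VolumeImage:
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return VolumeImage(data=data, spacing=spacing, affine=np.asarray(nii.affine))


def load_mask(path: str | Path) -> BrainMask:
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj) > 0.5
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return BrainMask(data=data, spacing=spacing, affine=np.asarray(nii.affine))
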