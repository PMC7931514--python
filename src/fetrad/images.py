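"""Core 3D SUV image container and NIfTI I/O.

All pipeline stages consume :class:`SUVImage`: a non-negative 3D grid of
standardized uptake values (g/ml) together with the voxel spacing in mm.
Grid indices are 0-based; a voxel's physical center is ``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["SUVImage", "save_mask", "load_mask", "sphere_mask"]


@dataclass(frozen=True)
class SUVImage:
    """A 3D standardized-uptake-value image.

    Parameters
    ----------
    values : ndarray
        3D array of SUV values (g/ml). Must be finite and non-negative.
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in mm, all components > 0.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={vals.ndim}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("SUV values must be finite")
        if np.any(vals < 0):
            raise ValueError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive components, got {spacing}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        return aff

    def save(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.values, self.affine()), path)

    @classmethod
    def load(cls, path: str) -> "SUVImage":
        img = nib.load(path)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), spacing)


def save_mask(mask: np.ndarray, image: SUVImage, path: str) -> None:
    """Write a binary mask as NIfTI on the image grid (uint8, image affine)."""
    if mask.shape != image.shape:
        raise ValueError("mask grid does not match image grid")
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), image.affine()), path)


def load_mask(path: str) -> np.ndarray:
    return np.asarray(nib.load(path).get_fdata()) > 0.5


def sphere_mask(
    shape: tuple[int, int, int],
    center_vox: tuple[float, float, float],
    radius_mm: float,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Binary ball: voxel included iff its center lies inside the sphere.

    Membership is the voxel-center-inside test (distance <= radius); no
    partial-volume weighting.
    """
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center_vox, spacing))
    return d2 <= radius_mm**2
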