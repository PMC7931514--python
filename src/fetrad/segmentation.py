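"""Three-step semi-automatic tumor contouring on FET-PET SUV images.

Step 1: the background SUV is estimated from two manually placed spheres
(cerebrum + cerebellum); step 2: voxels with SUV >= 1.8 x background form
``v_threshold``, from which a user-supplied exclusion mask removes non-tumor
uptake (vessels, extracerebral enhancement) to give ``v_pet``; step 3: two
derived contours — ``v_pet3mm`` (3 mm isotropic margin around v_pet,
analogous to a clinical target volume) and ``v_petmax`` (the contiguous
component containing the SUV maximum, the high-risk volume). A 4 cc
background reference sphere ``v_bg`` is placed disjoint from ``v_pet3mm``.

Conventions (documented constants): the threshold comparison is inclusive
(>=); contiguity is 26-connectivity (configurable to 6); the margin uses the
exact Euclidean distance transform so anisotropic voxels are handled
correctly; sphere membership is the voxel-center-inside test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import SUVImage, sphere_mask

__all__ = [
    "BackgroundEstimate",
    "ContourSet",
    "estimate_background",
    "threshold_segment",
    "apply_exclusion",
    "dilate_margin",
    "extract_max_component",
    "place_background_sphere",
    "segment_tumor",
]

DEFAULT_THRESHOLD_FACTOR = 1.8
DEFAULT_MARGIN_MM = 3.0
DEFAULT_BG_SPHERE_DIAMETER_MM = 30.0  # diameter of the two reference spheres
DEFAULT_BG_CONTOUR_VOLUME_CC = 4.0


class EmptySegmentationError(ValueError):
    """Raised when a stage that needs a PET-positive volume receives none."""


@dataclass(frozen=True)
class BackgroundEstimate:
    """Background SUV from two reference spheres (mean of the two sphere means)."""

    sphere_centers: tuple[tuple[float, float, float], tuple[float, float, float]]
    diameter_mm: float
    suv_bg: float

    def __post_init__(self) -> None:
        if self.suv_bg <= 0:
            raise ValueError("background SUV must be > 0")


@dataclass(frozen=True)
class ContourSet:
    """The contour family produced by one segmentation run."""

    v_threshold: np.ndarray
    v_pet: np.ndarray
    v_pet3mm: np.ndarray
    v_petmax: np.ndarray
    v_bg: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.v_petmax <= self.v_pet).all():
            raise ValueError("nesting violated: v_petmax must be a subset of v_pet")
        if not (self.v_pet <= self.v_pet3mm).all():
            raise ValueError("nesting violated: v_pet must be a subset of v_pet3mm")
        if not (self.v_pet <= self.v_threshold).all():
            raise ValueError("v_pet must be a subset of v_threshold")
        if self.v_bg is not None and (self.v_bg & self.v_pet3mm).any():
            raise ValueError("v_bg must be disjoint from v_pet3mm")


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def estimate_background(
    image: SUVImage,
    centers: tuple[tuple[float, float, float], tuple[float, float, float]],
    diameter_mm: float = DEFAULT_BG_SPHERE_DIAMETER_MM,
) -> BackgroundEstimate:
    """Mean-of-means background SUV from two reference spheres.

    The two spheres are averaged per sphere first; the estimate is the mean of
    the two per-sphere means, not the pooled voxel mean, so a size imbalance
    between the spheres does not weight the estimate.
    """
    r = diameter_mm / 2.0
    means = []
    for c in centers:
        for ci, n, s in zip(c, image.shape, image.spacing):
            if ci * s - r < -s / 2 or ci * s + r > (n - 0.5) * s:
                raise ValueError(f"background sphere at {c} exceeds the grid")
        m = sphere_mask(image.shape, c, r, image.spacing)
        if not m.any():
            raise ValueError(f"background sphere at {c} contains no voxel centers")
        means.append(float(image.values[m].mean()))
    return BackgroundEstimate(tuple(centers), float(diameter_mm), float(np.mean(means)))


def threshold_segment(
    image: SUVImage, bg: BackgroundEstimate, factor: float = DEFAULT_THRESHOLD_FACTOR
) -> np.ndarray:
    """Voxels with SUV >= factor x background SUV (inclusive comparison)."""
    if bg.suv_bg <= 0:
        raise ValueError("background SUV must be > 0")
    return image.values >= factor * bg.suv_bg


def apply_exclusion(v_threshold: np.ndarray, exclusion_mask: np.ndarray | None) -> np.ndarray:
    """Remove expert-identified non-tumor uptake: v_threshold AND NOT exclusion."""
    if exclusion_mask is None:
        return v_threshold.copy()
    if exclusion_mask.shape != v_threshold.shape:
        raise ValueError("exclusion mask grid does not match the segmentation grid")
    return v_threshold & ~exclusion_mask.astype(bool)


def dilate_margin(
    v_pet: np.ndarray,
    spacing: tuple[float, float, float],
    margin_mm: float = DEFAULT_MARGIN_MM,
) -> np.ndarray:
    """Expand a mask by a Euclidean margin in mm.

    A voxel is included iff the distance from its center to the nearest
    in-mask voxel center is <= margin_mm, computed with the exact Euclidean
    distance transform under the (possibly anisotropic) spacing.
    """
    if not v_pet.any():
        raise EmptySegmentationError("cannot dilate an empty PET-positive volume")
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0:
        return v_pet.copy()
    dist = ndimage.distance_transform_edt(~v_pet.astype(bool), sampling=spacing)
    return dist <= margin_mm


def extract_max_component(
    image: SUVImage, v_pet: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """The contiguous component of v_pet containing the global SUV maximum.

    Ties on the maximum are broken by the first maximal voxel in lexicographic
    index order.
    """
    if not v_pet.any():
        raise EmptySegmentationError("no PET-positive volume")
    labels, _ = ndimage.label(v_pet, structure=_connectivity_structure(connectivity))
    vals = np.where(v_pet, image.values, -np.inf)
    flat_idx = int(np.argmax(vals))  # argmax is lexicographically first on ties
    max_voxel = np.unravel_index(flat_idx, image.shape)
    return labels == labels[max_voxel]


def place_background_sphere(
    image: SUVImage,
    avoid: np.ndarray,
    volume_cc: float = DEFAULT_BG_CONTOUR_VOLUME_CC,
    clearance_mm: float = 2.0,
) -> np.ndarray:
    """Place the 4 cc background reference contour disjoint from ``avoid``.

    Deterministic: among voxel centers where the sphere fits inside the grid
    and clears the avoided mask, the one farthest from the avoided region is
    chosen (lexicographically first on ties), so reruns reproduce the mask.
    """
    r = float((3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))
    shape, spacing = image.shape, image.spacing
    if avoid.any():
        dist_avoid = ndimage.distance_transform_edt(~avoid.astype(bool), sampling=spacing)
    else:
        dist_avoid = np.full(shape, np.inf)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    border = [np.minimum(g, (s - 1) - g) * sp for g, s, sp in zip(grids, shape, spacing)]
    dist_border = np.minimum(np.minimum(border[0], border[1]), border[2])
    ok = (dist_border >= r) & (dist_avoid >= r + clearance_mm)
    if not ok.any():
        raise ValueError("no room to place the background reference sphere")
    score = np.where(ok, np.minimum(dist_avoid, np.inf), -np.inf)
    center = np.unravel_index(int(np.argmax(score)), shape)
    return sphere_mask(shape, center, r, spacing)


def segment_tumor(
    image: SUVImage,
    bg_centers,
    bg_diameter_mm: float = DEFAULT_BG_SPHERE_DIAMETER_MM,
    factor: float = DEFAULT_THRESHOLD_FACTOR,
    margin_mm: float = DEFAULT_MARGIN_MM,
    exclusion: np.ndarray | None = None,
    connectivity: int = 26,
    place_bg: bool = True,
) -> ContourSet:
    """Run the full three-step contouring and return the contour family."""
    bg = estimate_background(image, bg_centers, bg_diameter_mm)
    v_threshold = threshold_segment(image, bg, factor)
    v_pet = apply_exclusion(v_threshold, exclusion)
    if not v_pet.any():
        raise EmptySegmentationError("no PET-positive volume after exclusion")
    v_pet3mm = dilate_margin(v_pet, image.spacing, margin_mm)
    v_petmax = extract_max_component(image, v_pet, connectivity)
    v_bg = place_background_sphere(image, v_pet3mm) if place_bg else None
    return ContourSet(v_threshold, v_pet, v_pet3mm, v_petmax, v_bg)
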