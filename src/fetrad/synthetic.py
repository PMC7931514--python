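"""Synthetic stand-ins for patient scans, phantom scans and outcome cohorts.

Every downstream stage of the pipeline (segmentation, feature extraction,
screening, survival modelling) is exercised on data from this module, with
controllable ground truth:

* :func:`gen_brain_pet` — tumor-bearing brain PET: smooth uniform background
  plus hot lesions with controllable intra-lesion heterogeneity, blurred by a
  Gaussian point-spread function and degraded with additive Gaussian SUV noise.
* :func:`gen_nema_phantom` — a NEMA-like phantom: six fillable hot spheres
  (0.5-25 cc) in a warm background, rendered under a "scanner" profile
  (PSF width + noise level) so the same geometry can be imaged twice.
* :func:`gen_background_contours` — spherical contours placed in the phantom
  background with log-uniform volumes, used to probe feature size dependence.
* :func:`gen_cohort` — a feature-level cohort whose survival times follow a
  proportional-hazards model with known coefficients and whose
  recurrence-location label follows a logistic model on the features.

The noise model is additive Gaussian in SUV, not Poisson in counts: the
pipeline consumes reconstructed SUV images, for which this is sufficient for
robustness testing. Lesion heterogeneity is a multiplicative (1 + f) field
with f a zero-mean Gaussian random field, clipped below at 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import SUVImage, sphere_mask

__all__ = [
    "LesionSpec",
    "ScannerProfile",
    "CohortSpec",
    "NEMA_SPHERE_VOLUMES_CC",
    "gen_brain_pet",
    "gen_nema_phantom",
    "gen_background_contours",
    "gen_cohort",
]

#: Fillable-sphere volumes (cc) of the simulated calibration phantom,
#: matching the standard 10-37 mm sphere set, clipped to [0.5, 25] cc.
NEMA_SPHERE_VOLUMES_CC: tuple[float, ...] = (0.52, 1.15, 2.57, 5.58, 11.49, 25.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class LesionSpec:
    """A spherical hot lesion.

    center is in voxel coordinates; contrast is the multiple of the background
    SUV inside the lesion (must exceed 1); heterogeneity_sd is the standard
    deviation of the multiplicative Gaussian random field inside the lesion
    and texture_corr_mm its correlation length.
    """

    center: tuple[float, float, float]
    radius_mm: float
    contrast: float = 4.0
    heterogeneity_sd: float = 0.0
    texture_corr_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.contrast <= 1:
            raise ValueError("contrast must be > 1 (hot lesion)")


@dataclass(frozen=True)
class ScannerProfile:
    """Gaussian PSF width (FWHM, mm) and additive SUV noise level."""

    psf_fwhm_mm: float = 4.8
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm_mm and noise_sd must be >= 0")


def _blur(values: np.ndarray, fwhm_mm: float, spacing) -> np.ndarray:
    if fwhm_mm == 0:
        return values
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing]
    return ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")


def _heterogeneity_field(shape, spacing, sd, corr_mm, rng) -> np.ndarray:
    """Unit-mean multiplicative field 1 + f, f smoothed white noise with SD sd."""
    if sd == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    sigma_vox = [max(corr_mm / s, 1e-6) for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    f_sd = f.std()
    if f_sd > 0:
        f = f / f_sd * sd
    return np.clip(1.0 + f, 0.1, None)


def gen_brain_pet(
    bg_suv: float,
    lesions: list[LesionSpec],
    scanner: ScannerProfile,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
) -> tuple[SUVImage, np.ndarray]:
    """Render a tumor-bearing brain PET.

    Background voxels are ``bg_suv``; each lesion paints
    ``bg_suv * contrast * (1 + f)`` on its spherical support. The analytic
    image is convolved with the scanner PSF, then additive Gaussian noise is
    applied and the result clipped at zero.

    Returns the image and the pre-blur lesion support mask (the ground truth
    for segmentation recovery tests).
    """
    rng = np.random.default_rng(seed)
    values = np.full(grid_shape, float(bg_suv))
    truth = np.zeros(grid_shape, dtype=bool)
    for les in lesions:
        for c, n, s in zip(les.center, grid_shape, spacing):
            if c * s - les.radius_mm < 0 or c * s + les.radius_mm > (n - 1) * s:
                raise ValueError(f"lesion at {les.center} extends outside the grid")
        support = sphere_mask(grid_shape, les.center, les.radius_mm, spacing)
        fld = _heterogeneity_field(
            grid_shape, spacing, les.heterogeneity_sd, les.texture_corr_mm, rng
        )
        values[support] = bg_suv * les.contrast * fld[support]
        truth |= support
    values = _blur(values, scanner.psf_fwhm_mm, spacing)
    if scanner.noise_sd > 0:
        values = values + rng.normal(0.0, scanner.noise_sd, grid_shape)
    values = np.clip(values, 0.0, None)
    return SUVImage(values, spacing), truth


def _radius_from_volume_cc(volume_cc: float) -> float:
    return float((3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def gen_nema_phantom(
    sphere_volumes_cc: tuple[float, ...] = NEMA_SPHERE_VOLUMES_CC,
    sphere_to_bg_ratio: float = 4.0,
    scanner: ScannerProfile = ScannerProfile(),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    bg_suv: float = 1.0,
    grid_shape: tuple[int, int, int] = (150, 60, 60),
    seed: int = 0,
) -> tuple[SUVImage, list[np.ndarray]]:
    """Render the six-sphere calibration phantom under one scanner profile.

    The geometry (sphere layout) is a pure function of volumes/spacing, so the
    identical phantom can be imaged under two scanner profiles. Spheres sit in
    a row at the low-x end; the remaining grid is warm background available
    for :func:`gen_background_contours`. Geometry is simplified to spheres in
    a box: only sphere/background statistics matter downstream.
    """
    if len(sphere_volumes_cc) != 6:
        raise ValueError("the phantom has exactly 6 fillable spheres")
    for v in sphere_volumes_cc:
        if not (0.5 <= v <= 25.0):
            raise ValueError(f"sphere volume {v} cc outside the fillable range [0.5, 25]")
    if sphere_to_bg_ratio <= 1:
        raise ValueError("sphere_to_bg_ratio must be > 1 (hot spheres)")
    radii = [_radius_from_volume_cc(v) for v in sphere_volumes_cc]
    gap_mm = 6.0
    centers = []
    x_mm = 2.0 * spacing[0] + gap_mm
    yc = (grid_shape[1] - 1) / 2.0
    zc = (grid_shape[2] - 1) / 2.0
    for r in radii:
        x_mm += r
        centers.append((x_mm / spacing[0], yc, zc))
        x_mm += r + gap_mm
    values = np.full(grid_shape, float(bg_suv))
    masks = []
    for (cx, cy, cz), r in zip(centers, radii):
        m = sphere_mask(grid_shape, (cx, cy, cz), r, spacing)
        if not m.any() or m[0].any() or m[-1].any():
            raise ValueError("sphere layout does not fit the grid")
        values[m] = bg_suv * sphere_to_bg_ratio
        masks.append(m)
    for i in range(6):
        for j in range(i + 1, 6):
            if (masks[i] & masks[j]).any():
                raise ValueError("phantom spheres overlap")
    rng = np.random.default_rng(seed)
    values = _blur(values, scanner.psf_fwhm_mm, spacing)
    if scanner.noise_sd > 0:
        values = values + rng.normal(0.0, scanner.noise_sd, grid_shape)
    values = np.clip(values, 0.0, None)
    return SUVImage(values, spacing), masks


def gen_background_contours(
    image: SUVImage,
    n: int = 102,
    volume_range_cc: tuple[float, float] = (0.8, 234.0),
    seed: int = 0,
    avoid: np.ndarray | None = None,
    clearance_mm: float = 4.0,
) -> list[np.ndarray]:
    """Place ``n`` spherical contours in the image background.

    Volumes are log-uniform over ``volume_range_cc``. Each sphere lies fully
    inside the grid and keeps ``clearance_mm`` away from the ``avoid`` mask
    (e.g. the union of the phantom spheres); contours may overlap each other,
    as delineated background regions do.
    """
    rng = np.random.default_rng(seed)
    lo, hi = volume_range_cc
    if lo <= 0 or hi < lo:
        raise ValueError("invalid volume range")
    shape, spacing = image.shape, image.spacing
    if avoid is not None:
        dist_avoid = ndimage.distance_transform_edt(~avoid.astype(bool), sampling=spacing)
    else:
        dist_avoid = np.full(shape, np.inf)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    border = [np.minimum(g, (s - 1) - g) * sp for g, s, sp in zip(grids, shape, spacing)]
    dist_border = np.minimum(np.minimum(border[0], border[1]), border[2])
    volumes = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    masks = []
    for v in np.sort(volumes)[::-1]:  # place big spheres first: clearest failure
        r = _radius_from_volume_cc(v)
        ok = (dist_border >= r) & (dist_avoid >= r + clearance_mm)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            raise ValueError(
                f"cannot place a {v:.1f} cc sphere in the background without "
                "overlapping the avoided regions"
            )
        c = np.unravel_index(idx[rng.integers(idx.size)], shape)
        masks.append(sphere_mask(shape, c, r, spacing))
    return masks


@dataclass(frozen=True)
class CohortSpec:
    """Ground truth for a feature-level outcome cohort.

    Feature values are independent Normals per name; time-to-progression (TTP)
    and overall survival (OS) are exponential with hazard
    ``baseline_hazard * exp(beta' x)`` (proportional hazards with constant
    baseline — the Cox stage is hazard-shape-agnostic); independent
    exponential censoring is tuned to the requested expected censoring
    fraction; the recurrence-location label is Bernoulli with logit
    ``gamma' x + intercept`` and is defined only for subjects whose
    progression was observed.

    Defaults mirror the scale of a 32-patient re-irradiation cohort: median
    TTP ~ 91 days, median OS ~ 296 days, with the size-zone feature SZLGE
    driving both earlier progression and in-field recurrence.
    """

    n_subjects: int = 32
    feature_means: dict = field(
        default_factory=lambda: {
            "SZLGE": 0.0, "Busyness": 0.0, "QVariance_CM": 0.0, "Eccentricity": 0.0,
            "SUV_min": 0.0, "SUV_mean": 0.0, "WF_GLV": 0.0, "QLRHGE": 0.0,
        }
    )
    feature_sds: dict | None = None  # default: SD 1 for every feature
    cox_coefficients_ttp: dict = field(default_factory=lambda: {"SZLGE": 0.8})
    cox_coefficients_os: dict = field(default_factory=lambda: {"SUV_min": 0.5})
    baseline_hazard_ttp: float = float(np.log(2.0) / 91.0)
    baseline_hazard_os: float = float(np.log(2.0) / 296.5)
    censor_rate_ttp: float = 0.15
    censor_rate_os: float = 0.30
    rl_logistic_coefficients: dict = field(default_factory=lambda: {"SZLGE": 1.0})
    rl_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for c in (self.censor_rate_ttp, self.censor_rate_os):
            if not (0.0 <= c <= 1.0):
                raise ValueError("censor rates must lie in [0, 1]")
        names = set(self.feature_means)
        for coef in (self.cox_coefficients_ttp, self.cox_coefficients_os,
                     self.rl_logistic_coefficients):
            unknown = set(coef) - names
            if unknown:
                raise ValueError(f"coefficients refer to unknown features: {sorted(unknown)}")


def _censor_hazard(rates: np.ndarray, target: float) -> float:
    """Exponential censoring hazard c with mean_i c/(c+lambda_i) = target."""
    if target <= 0:
        return 0.0
    if target >= 1:
        return np.inf
    lo, hi = 1e-12, 1e12

    def frac(c):
        return float(np.mean(c / (c + rates)))

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from a :class:`CohortSpec`.

    Columns: ``subject_id``, one column per feature, ``ttp_days``,
    ``ttp_event``, ``os_days``, ``os_event``, ``rl_label`` (1 = recurrence
    inside the initial PET-positive volume; NaN where progression was not
    observed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    names = list(spec.feature_means)
    sds = spec.feature_sds or {}
    X = {name: rng.normal(spec.feature_means[name], sds.get(name, 1.0), n) for name in names}

    def linpred(coefs):
        lp = np.zeros(n)
        for name, b in coefs.items():
            lp += b * X[name]
        return lp

    out = {"subject_id": [f"S{i:03d}" for i in range(n)]}
    out.update(X)
    for endpoint, coefs, h0, crate in (
        ("ttp", spec.cox_coefficients_ttp, spec.baseline_hazard_ttp, spec.censor_rate_ttp),
        ("os", spec.cox_coefficients_os, spec.baseline_hazard_os, spec.censor_rate_os),
    ):
        haz = h0 * np.exp(linpred(coefs))
        t_event = rng.exponential(1.0 / haz)
        c_haz = _censor_hazard(haz, crate)
        if c_haz == 0.0:
            t_cens = np.full(n, np.inf)
        else:
            t_cens = rng.exponential(1.0 / c_haz, n)
        observed = t_event <= t_cens
        t = np.where(observed, t_event, t_cens)
        out[f"{endpoint}_days"] = np.maximum(t, 1e-9)
        out[f"{endpoint}_event"] = observed
    p_in = 1.0 / (1.0 + np.exp(-(linpred(spec.rl_logistic_coefficients) + spec.rl_intercept)))
    rl = (rng.uniform(size=n) < p_in).astype(float)
    rl[~np.asarray(out["ttp_event"])] = np.nan
    out["rl_label"] = rl
    return pd.DataFrame(out)
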