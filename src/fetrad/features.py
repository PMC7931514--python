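"""The 135-entry radiomics feature vector.

Catalogue composition (frozen, versioned manifest):

* 9 histogram features on raw SUV values in the contour (entropy/energy on
  the FBW-discretized histogram);
* 6 shape features from the binary mask and voxel spacing;
* 40 texture features from the four matrices (GLCM 9, GLRLM 13, GLSZM 13,
  NGTDM 5) on the FBW-discretized volume;
* the same 40 on the equal-probability-quantized volume (prefix ``Q``);
* the same 40 on the wavelet band-pass filtered volume, FBW-discretized
  (prefix ``WF_``).

9 + 6 + 3 x 40 = 135 named entries. Undefined features (degenerate ROIs)
are NaN, never silently dropped. Variance, skewness and kurtosis use
population (1/n) normalization; kurtosis is excess kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .images import SUVImage
from .preprocessing import (
    DiscretizationConfig,
    WaveletConfig,
    discretize_fbw,
    equal_probability_quantize,
    wavelet_bandpass,
)
from .texture import (
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "CATALOGUE_VERSION",
    "HISTOGRAM_NAMES",
    "SHAPE_NAMES",
    "TEXTURE_NAMES",
    "FEATURE_NAMES",
    "catalogue_manifest",
    "histogram_features",
    "shape_features",
    "texture_features",
    "compute_feature_vector",
    "FeatureExtractor",
]

CATALOGUE_VERSION = "fetrad-135-v1"

HISTOGRAM_NAMES = (
    "SUV_min", "SUV_max", "SUV_mean", "SUV_median",
    "Variance", "Skewness", "Kurtosis", "Energy_H", "Entropy_H",
)
SHAPE_NAMES = (
    "Volume_cc", "SurfaceArea", "Sphericity", "Compactness", "Eccentricity", "Elongation",
)
_GLCM_NAMES = (
    "Acor", "Variance_CM", "Energy_CM", "Contrast_CM", "Entropy_CM",
    "Homogeneity", "Correlation", "Dissimilarity", "SumAverage",
)
_GLRLM_NAMES = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV")
_GLSZM_NAMES = ("SZE", "LZE", "GLN2", "ZSN", "ZP", "LGZE", "HGZE",
                "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV2", "ZSV")
_NGTDM_NAMES = ("Coarseness", "Contrast_NGTDM", "Busyness", "Complexity", "TS")
TEXTURE_NAMES = _GLCM_NAMES + _GLRLM_NAMES + _GLSZM_NAMES + _NGTDM_NAMES

FEATURE_NAMES: tuple[str, ...] = (
    HISTOGRAM_NAMES
    + SHAPE_NAMES
    + TEXTURE_NAMES
    + tuple("Q" + n for n in TEXTURE_NAMES)
    + tuple("WF_" + n for n in TEXTURE_NAMES)
)
assert len(FEATURE_NAMES) == 135


def catalogue_manifest() -> dict:
    """The frozen feature-catalogue manifest (serialize as JSON)."""
    return {
        "version": CATALOGUE_VERSION,
        "n_features": len(FEATURE_NAMES),
        "histogram": list(HISTOGRAM_NAMES),
        "shape": list(SHAPE_NAMES),
        "texture_base": list(TEXTURE_NAMES),
        "variants": {"Q": "equal-probability quantization", "WF_": "wavelet band-pass"},
        "names": list(FEATURE_NAMES),
    }


def histogram_features(
    image: SUVImage, mask: np.ndarray, config: DiscretizationConfig = DiscretizationConfig()
) -> dict[str, float]:
    """First-order statistics on raw SUVs; entropy/energy on the FBW histogram."""
    if not mask.any():
        raise ValueError("empty mask")
    v = image.values[mask]
    disc = discretize_fbw(image, mask, config)
    counts = np.bincount(disc.levels[mask] - 1, minlength=disc.ng).astype(float)
    p = counts / counts.sum()
    pos = p > 0
    var = float(v.var())  # population normalization
    return {
        "SUV_min": float(v.min()),
        "SUV_max": float(v.max()),
        "SUV_mean": float(v.mean()),
        "SUV_median": float(np.median(v)),
        "Variance": var,
        "Skewness": float(stats.skew(v)) if var > 0 else float("nan"),
        "Kurtosis": float(stats.kurtosis(v)) if var > 0 else float("nan"),
        "Energy_H": float((p**2).sum()),
        "Entropy_H": float(-(p[pos] * np.log2(p[pos])).sum()),
    }


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """Geometry of the binary contour.

    Volume is voxel count x voxel volume. Surface area counts exposed voxel
    faces (face-counting method, recorded choice). Sphericity is
    pi^(1/3) (6V)^(2/3) / A and compactness 36 pi V^2 / A^3, both 1 for an
    ideal sphere. Eccentricity and elongation come from the eigenvalues of
    the voxel-center covariance (in mm): sqrt(1 - l_min / l_max) and
    sqrt(l_2 / l_max). Single-voxel masks have undefined axis features.
    """
    if not mask.any():
        raise ValueError("empty mask")
    n = int(mask.sum())
    voxvol = float(np.prod(spacing))
    volume_mm3 = n * voxvol
    area = 0.0
    for ax in range(3):
        face = voxvol / spacing[ax]
        pad = np.pad(mask, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        area += float(np.abs(np.diff(pad.astype(np.int8), axis=ax)).sum()) * face
    sphericity = float(np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / area)
    compactness = float(36 * np.pi * volume_mm3**2 / area**3)
    out = {
        "Volume_cc": volume_mm3 / 1000.0,
        "SurfaceArea": area,
        "Sphericity": sphericity,
        "Compactness": compactness,
        "Eccentricity": float("nan"),
        "Elongation": float("nan"),
    }
    if n > 1:
        coords = np.argwhere(mask) * np.asarray(spacing)
        cov = np.cov(coords, rowvar=False, bias=True)
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]  # descending
        lam = np.clip(lam, 0.0, None)
        if lam[0] > 0:
            out["Eccentricity"] = float(np.sqrt(1.0 - lam[2] / lam[0]))
            out["Elongation"] = float(np.sqrt(lam[1] / lam[0]))
    return out


def texture_features(disc, connectivity: int = 26) -> dict[str, float]:
    """All 40 matrix-derived features from one discretized volume."""
    out: dict[str, float] = {}
    out.update(glcm_features(build_glcm(disc)))
    out.update(glrlm_features(build_glrlm(disc)))
    out.update(glszm_features(build_glszm(disc, connectivity)))
    out.update(ngtdm_features(build_ngtdm(disc)))
    return out


@dataclass
class FeatureExtractor:
    """Computes feature vectors; caches the wavelet-filtered volume per image.

    The wavelet filter acts on the whole image, so when many contours are
    extracted from one image (phantom screening) the filtered volume is
    computed once and reused.
    """

    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    connectivity: int = 26
    _wf_cache: dict = field(default_factory=dict, repr=False)

    def _filtered(self, image: SUVImage) -> SUVImage:
        key = id(image)
        if key not in self._wf_cache:
            self._wf_cache.clear()  # hold at most one volume
            self._wf_cache[key] = wavelet_bandpass(image, self.wavelet)
        return self._wf_cache[key]

    def extract(self, image: SUVImage, mask: np.ndarray) -> dict[str, float]:
        """The full 135-entry vector for one (image, contour) pair."""
        if not mask.any():
            raise ValueError("empty mask")
        out: dict[str, float] = {}
        out.update(histogram_features(image, mask, self.discretization))
        out.update(shape_features(mask, image.spacing))
        base = texture_features(
            discretize_fbw(image, mask, self.discretization), self.connectivity
        )
        out.update(base)
        q = texture_features(
            equal_probability_quantize(image, mask, self.discretization.n_levels_quantization),
            self.connectivity,
        )
        out.update({"Q" + k: v for k, v in q.items()})
        try:
            filtered = self._filtered(image)
        except ValueError:
            # image too small for the wavelet support: the WF variants are
            # undefined and flagged, not dropped
            out.update({"WF_" + k: float("nan") for k in TEXTURE_NAMES})
        else:
            wf = texture_features(
                discretize_fbw(filtered, mask, self.discretization),
                self.connectivity,
            )
            out.update({"WF_" + k: v for k, v in wf.items()})
        vec = {name: out[name] for name in FEATURE_NAMES}
        assert len(vec) == 135
        return vec


def compute_feature_vector(
    image: SUVImage,
    mask: np.ndarray,
    discretization: DiscretizationConfig = DiscretizationConfig(),
    wavelet: WaveletConfig = WaveletConfig(),
    connectivity: int = 26,
) -> dict[str, float]:
    """One-shot feature vector (see :class:`FeatureExtractor` for batch use)."""
    return FeatureExtractor(discretization, wavelet, connectivity).extract(image, mask)
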