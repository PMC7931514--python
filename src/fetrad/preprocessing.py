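"""Intensity transforms applied before texture-matrix construction.

Three transforms feed the feature catalogue:

* fixed-bin-width (FBW) discretization with W = 0.01 SUV, anchored at the
  ROI minimum — the base discretization for all texture matrices;
* equal-probability quantization to 64 levels (the "Q" feature variants);
* one-level 3D wavelet band-pass filtering with a 1:2 weight ratio between
  the six mixed (band-pass) sub-bands and the LLL/HHH sub-bands (the "WF_"
  feature variants), after which the filtered volume is FBW-discretized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .images import SUVImage

__all__ = [
    "DiscretizationConfig",
    "DiscretizedVolume",
    "WaveletConfig",
    "discretize_fbw",
    "equal_probability_quantize",
    "wavelet_bandpass",
]


@dataclass(frozen=True)
class DiscretizationConfig:
    """FBW bin width (SUV) and equal-probability level count."""

    bin_width: float = 0.01
    n_levels_quantization: int = 64

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be > 0")
        if self.n_levels_quantization < 2:
            raise ValueError("quantization needs at least 2 levels")


@dataclass(frozen=True)
class DiscretizedVolume:
    """Integer gray levels 1..Ng on the ROI voxels (0 outside the mask)."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    origin_value: float = float("nan")
    bin_width: float = float("nan")

    def __post_init__(self) -> None:
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask grids differ")
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("empty ROI")
        if inside.min() < 1 or inside.max() != self.ng:
            raise ValueError("levels must span 1..Ng inside the mask")


def discretize_fbw(
    image: SUVImage, mask: np.ndarray, config: DiscretizationConfig = DiscretizationConfig()
) -> DiscretizedVolume:
    """Fixed-bin-width discretization anchored at the ROI minimum.

    level(x) = floor((SUV(x) - min_ROI) / W) + 1; the ROI maximum maps to
    Ng = floor((max - min) / W) + 1. Adding a constant to all ROI values
    leaves the level map unchanged.
    """
    if not mask.any():
        raise ValueError("empty mask")
    w = config.bin_width
    vals = image.values
    mn = float(vals[mask].min())
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[mask] = np.floor((vals[mask] - mn) / w).astype(np.int64) + 1
    ng = int(levels[mask].max())
    return DiscretizedVolume(levels, mask.astype(bool), ng, mn, w)


def equal_probability_quantize(
    image: SUVImage, mask: np.ndarray, n_levels: int = 64
) -> DiscretizedVolume:
    """Histogram-equalizing quantization (equal voxel count per level).

    Voxels are assigned levels by rank so each level holds as equal a count as
    ties permit; tied SUV values always share the level of their first sorted
    occurrence. Levels are then compacted to 1..Ng (empty levels dropped).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not mask.any():
        raise ValueError("empty mask")
    vals = image.values[mask]
    n = vals.size
    order = np.argsort(vals, kind="stable")
    lev_sorted = (np.arange(n) * n_levels) // n + 1
    # unify ties: every occurrence of a value takes the level of its first one
    first = np.empty(n, dtype=np.int64)
    first[0] = 0
    same = vals[order][1:] == vals[order][:-1]
    for i in range(1, n):
        first[i] = first[i - 1] if same[i - 1] else i
    lev_sorted = lev_sorted[first]
    raw = np.empty(n, dtype=np.int64)
    raw[order] = lev_sorted
    occupied, compact = np.unique(raw, return_inverse=True)
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[mask] = compact + 1
    return DiscretizedVolume(levels, mask.astype(bool), int(occupied.size))


@dataclass(frozen=True)
class WaveletConfig:
    """One-level 3D wavelet band-pass filter settings.

    ``bandpass_weight`` multiplies the six mixed sub-bands (those containing
    both low- and high-pass axes) relative to the LLL and HHH sub-bands,
    which keep weight 1 — so a unit weight is the identity (perfect
    reconstruction). The printed ratio "1:2" between band-pass and other
    sub-bands is ambiguous in orientation; the default attenuates the
    band-pass sub-bands by 1/2, and ``orientation='boost'`` selects the
    other reading (weight 2).
    """

    basis: str = "coif1"
    orientation: str = "attenuate"
    ratio: float = 2.0

    def bandpass_weight(self) -> float:
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")
        if self.orientation == "attenuate":
            return 1.0 / self.ratio
        if self.orientation == "boost":
            return float(self.ratio)
        raise ValueError("orientation must be 'attenuate' or 'boost'")


def wavelet_bandpass(image: SUVImage, config: WaveletConfig = WaveletConfig()) -> SUVImage:
    """One-level 3D DWT, re-weight the six mixed sub-bands, invert.

    Symmetric boundary padding; the output is cropped to the input shape and
    clipped at zero (SUV images are non-negative by contract).
    """
    wavelet = pywt.Wavelet(config.basis)
    min_len = wavelet.dec_len
    if any(s < min_len for s in image.shape):
        raise ValueError(
            f"image dimensions {image.shape} too small for wavelet '{config.basis}'"
        )
    w_bp = config.bandpass_weight()
    coeffs = pywt.dwtn(image.values, wavelet, mode="symmetric")
    for key in coeffs:
        if 0 < sum(ch == "d" for ch in key) < 3:  # mixed sub-band
            coeffs[key] = coeffs[key] * w_bp
    rec = pywt.idwtn(coeffs, wavelet, mode="symmetric")
    rec = rec[tuple(slice(0, s) for s in image.shape)]
    return SUVImage(np.clip(rec, 0.0, None), image.spacing)
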