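"""Phantom- and cohort-driven feature filters.

Four screens, mirroring the study design the pipeline implements:

* scanner robustness — paired Wilcoxon signed-rank over the same phantom
  contours rendered under two scanner profiles; a feature is robust when the
  test fails to reject at uncorrected alpha (Bonferroni is applied only to
  the tumor-vs-background family);
* size dependence — Spearman rank correlation of the feature against the
  voxel count over background contours; dependent when p < alpha AND
  |r| > 0.8 (negative strong correlation is equally disqualifying);
* tumor vs background — paired Wilcoxon per feature between a tumor contour
  and the 4 cc background sphere, Bonferroni-corrected over the family;
* added value — a feature adds information when it is NOT strongly
  Spearman-correlated with either SUV_max or volume.

The Wilcoxon signed-rank test uses the exact null distribution for n <= 25
pairs (no ties/zeros) and the tie-corrected normal approximation otherwise;
all pairwise-zero differences give the "robust with p = 1" convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreeningConfig",
    "wilcoxon_signed_rank",
    "spearman_strong_correlation",
    "scanner_robustness",
    "size_dependence",
    "tumor_vs_background",
    "added_value",
    "segment_phantom_sphere",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class ScreeningConfig:
    alpha: float = 0.05
    strong_corr_r: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.strong_corr_r < 1):
            raise ValueError("strong_corr_r must be in (0, 1)")


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p value.

    NaN pairs are dropped (undefined features propagate pairwise). All-zero
    differences return p = 1 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    if d.size == 0 or np.all(d == 0):
        return 1.0
    has_ties = (np.unique(np.abs(d[d != 0])).size < np.count_nonzero(d)) or np.any(d == 0)
    if d.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                         alternative="two-sided", method=method)
    return float(res.pvalue)


def spearman_strong_correlation(
    x: np.ndarray, y: np.ndarray, cfg: ScreeningConfig = ScreeningConfig()
) -> tuple[bool, float, float]:
    """(strongly correlated?, r, p) under the p < alpha AND |r| > 0.8 rule.

    Constant inputs make r undefined: returned as (False, nan, nan), the
    "independent with flag" convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
        return False, float("nan"), float("nan")
    r, p = stats.spearmanr(x[ok], y[ok])
    strong = bool(p < cfg.alpha and abs(r) > cfg.strong_corr_r)
    return strong, float(r), float(p)


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame(features)


def scanner_robustness(
    features_a, features_b, cfg: ScreeningConfig = ScreeningConfig()
) -> pd.DataFrame:
    """Paired signed-rank over contours rendered under two scanners.

    ``features_a``/``features_b`` hold one row per contour (same contours,
    same order) and one column per feature. Sphere and background contours
    are pooled into one test per feature. Robust <=> p >= alpha.
    """
    a = _as_frame(features_a)
    b = _as_frame(features_b)
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        raise ValueError("paired feature tables must share contours and columns")
    if len(a) < 6:
        raise ValueError("need at least 6 paired contours")
    rows = []
    for name in a.columns:
        p = wilcoxon_signed_rank(a[name].to_numpy(), b[name].to_numpy())
        rows.append({"feature": name, "p": p, "robust_scanner": p >= cfg.alpha})
    return pd.DataFrame(rows).set_index("feature")


def size_dependence(
    features, voxel_counts, cfg: ScreeningConfig = ScreeningConfig()
) -> pd.DataFrame:
    """Spearman correlation of each feature with contour voxel count."""
    f = _as_frame(features)
    v = np.asarray(voxel_counts, float)
    if len(f) != v.size:
        raise ValueError("one voxel count per contour required")
    if len(f) < 10 or v.max() / v.min() < 10:
        raise ValueError("need >= 10 contours spanning at least a decade of volume")
    rows = []
    for name in f.columns:
        strong, r, p = spearman_strong_correlation(f[name].to_numpy(), v, cfg)
        rows.append({"feature": name, "r": r, "p": p, "size_dependent": strong})
    return pd.DataFrame(rows).set_index("feature")


def tumor_vs_background(
    tumor_features, bg_features, cfg: ScreeningConfig = ScreeningConfig(),
    k: int | None = None,
) -> pd.DataFrame:
    """Per-feature paired signed-rank, Bonferroni threshold alpha / K.

    K defaults to the number of features tested (the family size).
    """
    t = _as_frame(tumor_features)
    b = _as_frame(bg_features)
    if list(t.columns) != list(b.columns) or len(t) != len(b):
        raise ValueError("paired per-subject tables must share subjects and columns")
    if len(t) < 6:
        raise ValueError("paired test degenerate below 6 subjects")
    k = k if k is not None else len(t.columns)
    thr = cfg.alpha / k
    rows = []
    for name in t.columns:
        p = wilcoxon_signed_rank(t[name].to_numpy(), b[name].to_numpy())
        rows.append({"feature": name, "p": p, "discriminates_tumor": p < thr})
    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["bonferroni_k"] = k
    return out


def added_value(
    features, suvmax, volume, cfg: ScreeningConfig = ScreeningConfig()
) -> pd.DataFrame:
    """Independence from the conventional indices SUV_max and volume."""
    f = _as_frame(features)
    if len(f) < 10:
        raise ValueError("need >= 10 subjects")
    suvmax = np.asarray(suvmax, float)
    volume = np.asarray(volume, float)
    rows = []
    for name in f.columns:
        x = f[name].to_numpy()
        s_suv, r_suv, p_suv = spearman_strong_correlation(x, suvmax, cfg)
        s_vol, r_vol, p_vol = spearman_strong_correlation(x, volume, cfg)
        rows.append({
            "feature": name,
            "r_suvmax": r_suv, "p_suvmax": p_suv,
            "r_volume": r_vol, "p_volume": p_vol,
            "independent_of_suvmax_volume": not (s_suv or s_vol),
        })
    return pd.DataFrame(rows).set_index("feature")


def segment_phantom_sphere(image, sphere_region: np.ndarray) -> np.ndarray:
    """Segment a fillable phantom sphere at 40% of its maximum uptake.

    ``sphere_region`` restricts the search to the neighborhood of one sphere
    (the analytic support, possibly dilated); the threshold is 40% of the
    maximum SUV inside that region, inclusive.
    """
    if not sphere_region.any():
        raise ValueError("empty sphere region")
    mx = float(image.values[sphere_region].max())
    return sphere_region & (image.values >= 0.4 * mx)
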