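"""3D texture matrices and their derived features.

Four matrices are built from a discretized ROI, following the standard 3D
(volumetric) definitions used in image-biomarker standardization work:

* GLCM  — gray-level co-occurrence over the 13 unique direction offsets at
  Chebyshev distance 1, symmetrized and pooled ("merged") into one matrix;
* GLRLM — maximal same-level runs along the same 13 directions, pooled;
* GLSZM — zones = 26-connected components of equal-level voxels;
* NGTDM — per-level occupancy p_i and summed absolute difference s_i between
  each voxel's level and the mean level of its in-mask 26-neighborhood.

Merging (pooling counts over directions before normalizing) rather than
averaging per-direction features is chosen for rotational stability; the
direction set is closed under the grid symmetries, so merged-matrix features
are invariant under axis permutations and reflections.

Degenerate inputs (single-voxel ROIs, single occupied level) yield NaN for
the affected features — an explicit "undefined" flag, never an exception —
so downstream statistics can drop them pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .preprocessing import DiscretizedVolume

__all__ = [
    "DIRECTIONS_13",
    "GLCM",
    "GLRLM",
    "GLSZM",
    "NGTDM",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_ngtdm",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "szlge",
    "ngtdm_busyness",
    "ngtdm_strength",
]

#: The 13 unique 3D offsets at Chebyshev distance 1 (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

_OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


def _offset_slices(shape, d):
    """Slice pair (src, dst) with dst = src + d, both inside the grid."""
    src, dst = [], []
    for n, c in zip(shape, d):
        if c == 1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        elif c == -1:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
        else:
            src.append(slice(0, n))
            dst.append(slice(0, n))
    return tuple(src), tuple(dst)


def _crop(disc: DiscretizedVolume):
    """Bounding-box crop of (levels, mask) — matrices only see the ROI."""
    idx = np.argwhere(disc.mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return disc.levels[sl], disc.mask[sl]


@dataclass(frozen=True)
class GLCM:
    """Merged, symmetric co-occurrence probabilities p(i, j), i, j in 1..Ng."""

    p: np.ndarray
    ng: int
    n_pairs: int


@dataclass(frozen=True)
class GLRLM:
    """Merged run counts P(i, r); p(i, r) = P / Nr."""

    counts: np.ndarray  # Ng x Rmax, integer counts
    ng: int
    n_runs: int
    n_voxels: int
    n_directions: int = len(DIRECTIONS_13)


@dataclass(frozen=True)
class GLSZM:
    """Zone counts P(i, s); p(i, s) = P / Nz."""

    counts: np.ndarray  # Ng x Smax, integer counts
    ng: int
    n_zones: int
    n_voxels: int


@dataclass(frozen=True)
class NGTDM:
    """Per-level occupancy p_i and neighborhood difference sum s_i."""

    p_i: np.ndarray  # length Ng, sums to 1
    s_i: np.ndarray  # length Ng, >= 0
    ng: int
    n_voxels: int


def build_glcm(disc: DiscretizedVolume) -> GLCM:
    """Pool co-occurrences over the 13 directions, symmetrize, normalize.

    Pairs with either voxel outside the mask are skipped. A single-voxel ROI
    has no pairs: the matrix is all-zero and features on it are undefined.
    """
    lv, m = _crop(disc)
    ng = disc.ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in DIRECTIONS_13:
        src, dst = _offset_slices(lv.shape, d)
        ok = m[src] & m[dst]
        a = lv[src][ok] - 1
        b = lv[dst][ok] - 1
        np.add.at(counts, (a, b), 1)
    counts = counts + counts.T  # both orders of each pair
    total = int(counts.sum())
    p = counts / total if total > 0 else counts.astype(float)
    return GLCM(p, ng, total)


def _run_lengths(lv: np.ndarray, m: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel run length along +d and the successor-in-run indicator."""
    shape = lv.shape
    src, dst = _offset_slices(shape, d)
    ns = np.zeros(shape, dtype=bool)  # ns[x]: x+d exists, in mask, same level
    ns[src] = m[src] & m[dst] & (lv[src] == lv[dst])
    L = np.zeros(shape, dtype=np.int64)
    k = next(i for i in range(3) if d[i])
    dk = d[k]
    order = range(shape[k] - 1, -1, -1) if dk > 0 else range(shape[k])
    full = [slice(None)] * 3
    sub_d = tuple(d[a] for a in range(3) if a != k)
    for i in order:
        j = i + dk
        sl_i = tuple(full[:k] + [i] + full[k + 1 :])
        cur = m[sl_i].astype(np.int64)
        if 0 <= j < shape[k]:
            sl_j = tuple(full[:k] + [j] + full[k + 1 :])
            ssrc, sdst = _offset_slices(cur.shape, sub_d)
            add = np.zeros_like(cur)
            add[ssrc] = ns[sl_i][ssrc] * L[sl_j][sdst]
            cur = cur + add
        L[sl_i] = cur
    return L, ns


def build_glrlm(disc: DiscretizedVolume) -> GLRLM:
    """Count maximal same-level runs along each of the 13 directions, pooled."""
    lv, m = _crop(disc)
    ng = disc.ng
    n_vox = int(m.sum())
    rmax = max(lv.shape)
    counts = np.zeros((ng, rmax), dtype=np.int64)
    for d in DIRECTIONS_13:
        L, ns = _run_lengths(lv, m, d)
        # run start: in-mask voxel whose predecessor x-d is not in the same run
        ps = np.zeros(lv.shape, dtype=bool)
        src, dst = _offset_slices(lv.shape, d)
        ps[dst] = ns[src]
        starts = m & ~ps
        np.add.at(counts, (lv[starts] - 1, L[starts] - 1), 1)
    n_runs = int(counts.sum())
    return GLRLM(counts, ng, n_runs, n_vox)


def build_glszm(disc: DiscretizedVolume, connectivity: int = 26) -> GLSZM:
    """Zones are connected components of equal-level voxels within the mask."""
    lv, m = _crop(disc)
    ng = disc.ng
    n_vox = int(m.sum())
    structure = (
        np.ones((3, 3, 3), dtype=bool)
        if connectivity == 26
        else ndimage.generate_binary_structure(3, 1)
    )
    zones: list[tuple[int, int]] = []
    smax = 1
    for g in np.unique(lv[m]):
        labels, n_lab = ndimage.label((lv == g) & m, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        smax = max(smax, int(sizes.max()))
        zones.extend((int(g), int(s)) for s in sizes)
    counts = np.zeros((ng, smax), dtype=np.int64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return GLSZM(counts, ng, len(zones), n_vox)


def build_ngtdm(disc: DiscretizedVolume) -> NGTDM:
    """Accumulate |level - neighborhood mean| per level over the masked ROI.

    The neighborhood is the 26-neighborhood restricted to the mask; a voxel
    with no in-mask neighbor contributes zero difference but still counts in
    the occupancy p_i.
    """
    lv, m = _crop(disc)
    ng = disc.ng
    n_vox = int(m.sum())
    nsum = np.zeros(lv.shape, dtype=np.float64)
    ncnt = np.zeros(lv.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        src, dst = _offset_slices(lv.shape, d)
        ok = m[dst]
        np.add.at(nsum[src], np.nonzero(ok), lv[dst][ok])
        ncnt[src] += ok
    diffs = np.zeros(lv.shape)
    has = m & (ncnt > 0)
    diffs[has] = np.abs(lv[has] - nsum[has] / ncnt[has])
    s_i = np.zeros(ng)
    np.add.at(s_i, lv[m] - 1, diffs[m])
    occ = np.bincount(lv[m] - 1, minlength=ng).astype(float)
    return NGTDM(occ / n_vox, s_i, ng, n_vox)


# --------------------------------------------------------------------------
# derived features
# --------------------------------------------------------------------------

_NAN = float("nan")


def glcm_features(g: GLCM) -> dict[str, float]:
    if g.n_pairs == 0:
        return {k: _NAN for k in (
            "Acor", "Variance_CM", "Energy_CM", "Contrast_CM", "Entropy_CM",
            "Homogeneity", "Correlation", "Dissimilarity", "SumAverage",
        )}
    p = g.p
    i = np.arange(1, g.ng + 1)[:, None]
    j = np.arange(1, g.ng + 1)[None, :]
    mu = float((i * p).sum())  # marginal mean; symmetric, so mu_i == mu_j
    var = float(((i - mu) ** 2 * p).sum())
    pos = p > 0
    out = {
        "Acor": float((i * j * p).sum()),
        "Variance_CM": var,
        "Energy_CM": float((p**2).sum()),
        "Contrast_CM": float(((i - j) ** 2 * p).sum()),
        "Entropy_CM": float(-(p[pos] * np.log2(p[pos])).sum()),
        "Homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "Dissimilarity": float((np.abs(i - j) * p).sum()),
        "SumAverage": float(((i + j) * p).sum()),
    }
    if var > 0:
        out["Correlation"] = float((((i - mu) * (j - mu) * p).sum()) / var)
    else:
        out["Correlation"] = _NAN
    return out


def glrlm_features(r: GLRLM) -> dict[str, float]:
    names = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
             "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV")
    if r.n_runs == 0:
        return {k: _NAN for k in names}
    P = r.counts.astype(float)
    nr = float(r.n_runs)
    p = P / nr
    i = np.arange(1, r.ng + 1)[:, None].astype(float)
    rl = np.arange(1, P.shape[1] + 1)[None, :].astype(float)
    mu_i = float((p * i).sum())
    mu_r = float((p * rl).sum())
    return {
        "SRE": float((p / rl**2).sum()),
        "LRE": float((p * rl**2).sum()),
        "GLN": float((P.sum(axis=1) ** 2).sum() / nr**2),
        "RLN": float((P.sum(axis=0) ** 2).sum() / nr**2),
        "RP": float(nr / (r.n_voxels * r.n_directions)),
        "LGRE": float((p / i**2).sum()),
        "HGRE": float((p * i**2).sum()),
        "SRLGE": float((p / (i**2 * rl**2)).sum()),
        "SRHGE": float((p * i**2 / rl**2).sum()),
        "LRLGE": float((p * rl**2 / i**2).sum()),
        "LRHGE": float((p * i**2 * rl**2).sum()),
        "GLV": float((p * (i - mu_i) ** 2).sum()),
        "RLV": float((p * (rl - mu_r) ** 2).sum()),
    }


def glszm_features(z: GLSZM) -> dict[str, float]:
    names = ("SZE", "LZE", "GLN2", "ZSN", "ZP", "LGZE", "HGZE",
             "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV2", "ZSV")
    if z.n_zones == 0:
        return {k: _NAN for k in names}
    P = z.counts.astype(float)
    nz = float(z.n_zones)
    p = P / nz
    i = np.arange(1, z.ng + 1)[:, None].astype(float)
    s = np.arange(1, P.shape[1] + 1)[None, :].astype(float)
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    return {
        "SZE": float((p / s**2).sum()),
        "LZE": float((p * s**2).sum()),
        "GLN2": float((P.sum(axis=1) ** 2).sum() / nz**2),
        "ZSN": float((P.sum(axis=0) ** 2).sum() / nz**2),
        "ZP": float(nz / z.n_voxels),
        "LGZE": float((p / i**2).sum()),
        "HGZE": float((p * i**2).sum()),
        "SZLGE": float((p / (i**2 * s**2)).sum()),
        "SZHGE": float((p * i**2 / s**2).sum()),
        "LZLGE": float((p * s**2 / i**2).sum()),
        "LZHGE": float((p * i**2 * s**2).sum()),
        "GLV2": float((p * (i - mu_i) ** 2).sum()),
        "ZSV": float((p * (s - mu_s) ** 2).sum()),
    }


def szlge(z: GLSZM) -> float:
    """Small-Zone Low-Gray-Level Emphasis: sum p(i, s) / (i^2 s^2)."""
    return glszm_features(z)["SZLGE"]


def ngtdm_features(t: NGTDM) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity and Strength (TS).

    Pair sums run over ordered pairs of occupied levels. Features whose
    denominators vanish (single occupied level, or zero total difference) are
    returned as NaN — the degenerate-ROI "undefined" flag.
    """
    occ = t.p_i > 0
    lv = np.arange(1, t.ng + 1, dtype=float)
    i = lv[occ]
    p = t.p_i[occ]
    s = t.s_i[occ]
    n_occ = int(occ.sum())
    ps_sum = float((t.p_i * t.s_i).sum())
    s_sum = float(t.s_i.sum())
    out = {
        "Coarseness": float(1.0 / ps_sum) if ps_sum > 0 else _NAN,
        "Contrast_NGTDM": _NAN,
        "Busyness": _NAN,
        "Complexity": _NAN,
        "TS": _NAN,
    }
    if n_occ >= 2:
        di = i[:, None] - i[None, :]
        pp = p[:, None] * p[None, :]
        out["Contrast_NGTDM"] = float(
            (pp * di**2).sum() / (n_occ * (n_occ - 1)) * (s_sum / t.n_voxels)
        )
        denom = float(np.abs(i[:, None] * p[:, None] - i[None, :] * p[None, :]).sum())
        if denom > 0:
            out["Busyness"] = ps_sum / denom
        psum = p[:, None] + p[None, :]
        pis = (p * s)[:, None] + (p * s)[None, :]
        mask_od = ~np.eye(n_occ, dtype=bool)
        out["Complexity"] = float(
            (np.abs(di[mask_od]) * pis[mask_od] / psum[mask_od]).sum() / t.n_voxels
        )
        if s_sum > 0:
            out["TS"] = float((psum * di**2).sum() / s_sum)
    return out


def ngtdm_busyness(t: NGTDM) -> float:
    return ngtdm_features(t)["Busyness"]


def ngtdm_strength(t: NGTDM) -> float:
    """Texture strength (TS)."""
    return ngtdm_features(t)["TS"]
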