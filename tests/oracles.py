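"""Independent brute-force oracles for the texture, geometry and survival code.

Everything here is written as literal, loop-based enumeration — no shared
code with the package implementation — so agreement between the two routes
is evidence of correctness, not of shared bugs.
"""

from __future__ import annotations

from itertools import product

import numpy as np

DIRS_13 = [d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
OFFS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def brute_glcm(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric merged co-occurrence probabilities by explicit pair listing."""
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for x in np.argwhere(mask):
        for d in DIRS_13:
            y = tuple(x + d)
            if _inside(shape, y) and mask[y]:
                i, j = levels[tuple(x)] - 1, levels[y] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def brute_glrlm(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Merged run counts by walking every line in every direction."""
    shape = levels.shape
    rmax = max(shape)
    counts = np.zeros((ng, rmax), dtype=int)
    for d in DIRS_13:
        for x in np.argwhere(mask):
            prev = tuple(x - d)
            # run start: predecessor missing, out of mask, or different level
            if _inside(shape, prev) and mask[prev] and levels[prev] == levels[tuple(x)]:
                continue
            g = levels[tuple(x)]
            length = 1
            nxt = tuple(x + d)
            while _inside(shape, nxt) and mask[nxt] and levels[nxt] == g:
                length += 1
                nxt = tuple(np.array(nxt) + d)
            counts[g - 1, length - 1] += 1
    return counts


def brute_glszm(levels: np.ndarray, mask: np.ndarray, ng: int,
                connectivity: int = 26) -> np.ndarray:
    """Zone counts by flood fill over equal-level voxels."""
    offs = OFFS_26 if connectivity == 26 else [
        d for d in OFFS_26 if sum(abs(c) for c in d) == 1
    ]
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        g = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for d in offs:
                w = tuple(np.array(v) + d)
                if (_inside(levels.shape, w) and mask[w] and not seen[w]
                        and levels[w] == g):
                    seen[w] = True
                    stack.append(w)
        zones.append((g, size))
    smax = max((s for _, s in zones), default=1)
    counts = np.zeros((ng, smax), dtype=int)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return counts


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray, ng: int):
    """(p_i, s_i) by per-voxel neighborhood loops."""
    n_vox = int(mask.sum())
    s = np.zeros(ng)
    occ = np.zeros(ng)
    for x in map(tuple, np.argwhere(mask)):
        g = levels[x]
        occ[g - 1] += 1
        nb = []
        for d in OFFS_26:
            y = tuple(np.array(x) + d)
            if _inside(levels.shape, y) and mask[y]:
                nb.append(levels[y])
        if nb:
            s[g - 1] += abs(g - sum(nb) / len(nb))
    return occ / n_vox, s


def brute_glszm_features(counts: np.ndarray) -> dict:
    """Literal sums over enumerated zones."""
    nz = counts.sum()
    out = {}
    szlge = hgze = szhge = gln2 = 0.0
    mu = 0.0
    for i in range(counts.shape[0]):
        for sidx in range(counts.shape[1]):
            p = counts[i, sidx] / nz
            lvl, size = i + 1, sidx + 1
            szlge += p / (lvl**2 * size**2)
            hgze += p * lvl**2
            szhge += p * lvl**2 / size**2
            mu += p * lvl
    for i in range(counts.shape[0]):
        gln2 += counts[i, :].sum() ** 2
    out["SZLGE"] = szlge
    out["HGZE"] = hgze
    out["SZHGE"] = szhge
    out["GLN2"] = gln2 / nz**2
    glv2 = 0.0
    for i in range(counts.shape[0]):
        for sidx in range(counts.shape[1]):
            glv2 += counts[i, sidx] / nz * (i + 1 - mu) ** 2
    out["GLV2"] = glv2
    return out


def brute_busyness_strength(p_i: np.ndarray, s_i: np.ndarray):
    """Direct double loops over occupied levels; NaN when degenerate."""
    occ = [i for i in range(len(p_i)) if p_i[i] > 0]
    if len(occ) < 2:
        return float("nan"), float("nan")
    num = sum(p_i[i] * s_i[i] for i in occ)
    den = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in occ for j in occ)
    busy = num / den if den > 0 else float("nan")
    s_sum = sum(s_i[i] for i in occ)
    if s_sum > 0:
        strength = sum(
            (p_i[i] + p_i[j]) * ((i + 1) - (j + 1)) ** 2 for i in occ for j in occ
        ) / s_sum
    else:
        strength = float("nan")
    return busy, strength


def naive_dilate(mask: np.ndarray, spacing, margin_mm: float) -> np.ndarray:
    """All-pairs Euclidean dilation (quadratic; tiny fixtures only)."""
    pts = np.argwhere(mask) * np.asarray(spacing)
    out = np.zeros(mask.shape, dtype=bool)
    for x in np.ndindex(mask.shape):
        c = np.asarray(x) * np.asarray(spacing)
        if np.any(np.sqrt(((pts - c) ** 2).sum(axis=1)) <= margin_mm):
            out[x] = True
    return out


def analytic_ball_voxels(shape, center, radius_mm, spacing) -> int:
    """Count voxel centers inside the analytic sphere (<= radius)."""
    n = 0
    for x in np.ndindex(shape):
        d2 = sum(((x[i] - center[i]) * spacing[i]) ** 2 for i in range(3))
        if d2 <= radius_mm**2:
            n += 1
    return n


def hand_logrank(time, event, group):
    """Risk-table log-rank chi-square by literal tabulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    o_e, var = 0.0, 0.0
    for t in sorted(set(time[event])):
        n = int((time >= t).sum())
        n1 = int(((time >= t) & group).sum())
        d = int((event & (time == t)).sum())
        d1 = int((event & (time == t) & group).sum())
        o_e += d1 - d * n1 / n
        if n > 1:
            var += d * n1 * (n - n1) * (n - d) / (n**2 * (n - 1))
    return o_e**2 / var if var > 0 else 0.0


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p by full enumeration (n <= 18)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    # null: each rank is + with probability 1/2; enumerate via bit masks
    total = 2**n
    stats_all = np.zeros(total)
    for bits in range(total):
        w = 0.0
        for i in range(n):
            if bits >> i & 1:
                w += ranks[i]
        stats_all[bits] = w
    mean_w = ranks.sum() / 2
    dev = abs(w_plus - mean_w)
    p = np.mean(np.abs(stats_all - mean_w) >= dev - 1e-12)
    return float(p)
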