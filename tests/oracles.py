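"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plain Python loops over voxels/pairs with
no shared code with the package: slow, obvious, and easy to audit.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

DIRS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def glcm_matrix(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Average of direction-wise normalized symmetric co-occurrence counts."""
    lo = int(min(levels[tuple(v)] for v in np.argwhere(mask)))
    hi = int(max(levels[tuple(v)] for v in np.argwhere(mask)))
    size = hi - lo + 1
    acc = np.zeros((size, size))
    used = 0
    shape = mask.shape
    for d in DIRS_13:
        counts = np.zeros((size, size))
        for x, y, z in product(*map(range, shape)):
            if not mask[x, y, z]:
                continue
            nx, ny, nz = x + d[0], y + d[1], z + d[2]
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2] \
                    and mask[nx, ny, nz]:
                a = levels[x, y, z] - lo
                b = levels[nx, ny, nz] - lo
                counts[a, b] += 1
                counts[b, a] += 1
        if counts.sum() > 0:
            acc += counts / counts.sum()
            used += 1
    return acc / used, lo


def glcm_features(p: np.ndarray) -> dict[str, float]:
    size = p.shape[0]
    mu_i = sum((i + 1) * p[i, j] for i in range(size) for j in range(size))
    mu_j = sum((j + 1) * p[i, j] for i in range(size) for j in range(size))
    var_i = sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(size) for j in range(size))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(size) for j in range(size))
    out = {
        "GLCM_variance": var_i,
        "GLCM_energy": sum(p[i, j] ** 2 for i in range(size) for j in range(size)),
        "GLCM_entropy": -sum(
            p[i, j] * math.log2(p[i, j])
            for i in range(size) for j in range(size) if p[i, j] > 0
        ),
        "GLCM_dissimilarity": sum(
            abs(i - j) * p[i, j] for i in range(size) for j in range(size)
        ),
        "GLCM_contrast": sum(
            (i - j) ** 2 * p[i, j] for i in range(size) for j in range(size)
        ),
        "GLCM_homogeneity": sum(
            p[i, j] / (1 + abs(i - j)) for i in range(size) for j in range(size)
        ),
        "GLCM_IDM": sum(
            p[i, j] / (1 + (i - j) ** 2) for i in range(size) for j in range(size)
        ),
        "GLCM_cluster_shade": sum(
            (i + j + 2 - mu_i - mu_j) ** 3 * p[i, j]
            for i in range(size) for j in range(size)
        ),
        "GLCM_cluster_tendency": sum(
            (i + j + 2 - mu_i - mu_j) ** 2 * p[i, j]
            for i in range(size) for j in range(size)
        ),
    }
    if var_i > 0 and var_j > 0:
        out["GLCM_correlation"] = sum(
            (i + 1 - mu_i) * (j + 1 - mu_j) * p[i, j]
            for i in range(size) for j in range(size)
        ) / math.sqrt(var_i * var_j)
    else:
        out["GLCM_correlation"] = float("nan")
    return out


def flood_fill_zones(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """(gray level, zone size) of every 26-connected same-level zone."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        level = levels[start]
        stack, members = [start], 0
        seen[start] = True
        while stack:
            v = stack.pop()
            members += 1
            for d in NEIGHBORS_26:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[k] < shape[k] for k in range(3)) and mask[w] \
                        and not seen[w] and levels[w] == level:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(level), members))
    return zones


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    zones = flood_fill_zones(levels, mask)
    n = len(zones)
    nv = int(mask.sum())
    feats = {
        "GLSZM_SZE": 0.0, "GLSZM_LZE": 0.0, "GLSZM_LGZE": 0.0,
        "GLSZM_HGZE": 0.0, "GLSZM_SZLGE": 0.0, "GLSZM_LZLGE": 0.0,
        "GLSZM_SZHGE": 0.0, "GLSZM_LZHGE": 0.0,
    }
    for level, size in zones:
        i, j = level + 1, size  # formula levels are 1-based
        feats["GLSZM_SZE"] += 1.0 / j**2
        feats["GLSZM_LZE"] += float(j**2)
        feats["GLSZM_LGZE"] += 1.0 / i**2
        feats["GLSZM_HGZE"] += float(i**2)
        feats["GLSZM_SZLGE"] += 1.0 / (i**2 * j**2)
        feats["GLSZM_LZLGE"] += j**2 / i**2
        feats["GLSZM_SZHGE"] += i**2 / j**2
        feats["GLSZM_LZHGE"] += float(i**2 * j**2)
    feats = {k: v / n for k, v in feats.items()}
    by_level: dict[int, int] = {}
    by_size: dict[int, int] = {}
    for level, size in zones:
        by_level[level] = by_level.get(level, 0) + 1
        by_size[size] = by_size.get(size, 0) + 1
    feats["GLSZM_ZP"] = n / nv
    feats["GLSZM_GLNUz"] = sum(c**2 for c in by_level.values()) / n
    feats["GLSZM_ZLNU"] = sum(c**2 for c in by_size.values()) / n
    return feats


def gldm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    shape = mask.shape
    per_level_s: dict[int, float] = {}
    per_level_n: dict[int, int] = {}
    for v in map(tuple, np.argwhere(mask)):
        neigh = []
        for d in NEIGHBORS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if all(0 <= w[k] < shape[k] for k in range(3)) and mask[w]:
                neigh.append(levels[w])
        if not neigh:
            continue
        lev = int(levels[v])
        per_level_s[lev] = per_level_s.get(lev, 0.0) + abs(
            lev - sum(neigh) / len(neigh)
        )
        per_level_n[lev] = per_level_n.get(lev, 0) + 1
    n = sum(per_level_n.values())
    present = sorted(per_level_n)
    p = {lev: per_level_n[lev] / n for lev in present}
    s = {lev: per_level_s[lev] for lev in present}
    ng = len(present)
    ps = sum(p[l] * s[l] for l in present)
    coarseness = min(1.0 / ps, 1.0e6) if ps > 0 else 1.0e6
    if ng > 1:
        contrast = (
            sum(
                p[a] * p[b] * (a - b) ** 2
                for a in present for b in present
            ) / (ng * (ng - 1))
        ) * (sum(s.values()) / n)
        busy_den = sum(
            abs((a + 1) * p[a] - (b + 1) * p[b]) for a in present for b in present
        )
        busyness = ps / busy_den if busy_den > 0 else float("nan")
        complexity = sum(
            abs(a - b) * (p[a] * s[a] + p[b] * s[b]) / (p[a] + p[b])
            for a in present for b in present
        ) / n
        s_total = sum(s.values())
        strength = (
            sum((p[a] + p[b]) * (a - b) ** 2 for a in present for b in present)
            / s_total if s_total > 0 else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, float("nan"), 0.0, 0.0
    return {
        "GLDM_coarseness": coarseness,
        "GLDM_contrast": contrast,
        "GLDM_busyness": busyness,
        "GLDM_complexity": complexity,
        "GLDM_strength": strength,
    }


def texture_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 26 texture indices by brute force."""
    p, _ = glcm_matrix(levels, mask)
    out = glcm_features(p)
    out.update(glszm_features(levels, mask))
    out.update(gldm_features(levels, mask))
    return out


def moments(values: np.ndarray) -> dict[str, float]:
    """Direct-summation mean/SD/skewness/kurtosis (population, non-excess)."""
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    sd = math.sqrt(m2)
    if sd == 0:
        return {"mean": mean, "sd": 0.0, "skewness": float("nan"),
                "kurtosis": float("nan")}
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    return {"mean": mean, "sd": sd, "skewness": m3 / sd**3, "kurtosis": m4 / m2**2}


def auc_u_statistic(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise AUC with 0.5 credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if sp > sn else 0.5 if sp == sn else 0.0 for sp in pos for sn in neg
    )
    return wins / (len(pos) * len(neg))


def altman_minimal_p(p_min: float, eps: float = 0.05) -> float:
    """Second, independent transcription of the minimal-P correction."""
    from scipy.stats import norm

    z = norm.ppf(1.0 - p_min / 2.0)
    phi = math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    log_term = math.log(((1.0 - eps) / eps) ** 2)
    return phi * (z - 1.0 / z) * log_term + 4.0 * phi / z


def wilcoxon_exact_two_sided(diffs: np.ndarray) -> float:
    """Exact signed-rank P by enumerating all 2^n sign patterns (no ties)."""
    n = len(diffs)
    ranks = {}
    for r, k in enumerate(sorted(range(n), key=lambda k: abs(diffs[k])), start=1):
        ranks[k] = r
    w_obs = sum(ranks[k] for k in range(n) if diffs[k] > 0)
    total = 2**n
    stats = []
    for pattern in range(total):
        w = sum(ranks[k] for k in range(n) if pattern >> k & 1)
        stats.append(w)
    mean_w = n * (n + 1) / 4.0
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in stats if abs(w - mean_w) >= dev - 1e-12)
    return extreme / total
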