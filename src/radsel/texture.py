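"""Texture matrices and the 26 texture indices on a quantized tumor region.

Three constructions are computed on the integer gray levels produced by
absolute resampling:

* gray-level co-occurrence matrix (GLCM): joint distribution of level
  pairs at distance 1, averaged over the 13 unique 3D directions;
* gray-level size-zone matrix (GLSZM): counts of maximal same-level
  connected zones (26-connectivity) by zone size;
* gray-level difference construction (GLDM, Amadasun-style neighborhood
  gray-tone difference): per-level occurrence probability p_i and summed
  absolute difference s_i between each voxel and the mean of its masked
  26-neighbors, yielding coarseness, contrast, busyness, complexity and
  strength.

Gray levels enter the weighted formulas 1-based (formula level =
quantized level + 1), so a region quantized to level 0 never divides by
zero. Absent intermediate levels are kept as zero rows. Features whose
denominator vanishes on a degenerate region (GLCM correlation on a flat
matrix, busyness on a single-level region) are returned as NaN, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateRegionError
from .feature_extraction import QuantizedVolume

#: the 13 unique 3D direction offsets at Chebyshev distance 1
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: cap applied to coarseness when its denominator underflows
COARSENESS_MAX = 1.0e6


@dataclass(frozen=True)
class CoocMatrix:
    """Normalized symmetric co-occurrence matrix averaged over directions.

    Row/column index k corresponds to quantized level ``min_level + k``.
    """

    matrix: np.ndarray
    min_level: int


@dataclass(frozen=True)
class SizeZoneMatrix:
    """Zone counts by (gray level, zone size); level index is 1-based."""

    matrix: np.ndarray  # shape (n_levels, max_zone_size)
    levels: np.ndarray  # formula (1-based) level per row
    total_zones: int
    total_voxels: int


@dataclass(frozen=True)
class NeighborhoodDifferenceTable:
    """Per-level occurrence probability and neighborhood-difference sums."""

    levels: np.ndarray  # formula (1-based) level values with p > 0
    p: np.ndarray  # occurrence probabilities, sum to 1
    s: np.ndarray  # summed |level - mean(masked neighbors)| per level
    n_valid: int  # voxels with at least one masked neighbor


def _offset_pairs(q: QuantizedVolume, offset: tuple[int, int, int]):
    """Levels of all within-mask voxel pairs at the given offset."""
    lev, m = q.levels, q.mask
    sl_a, sl_b = [], []
    for d in offset:
        if d == 0:
            sl_a.append(slice(None)), sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(None, -d)), sl_b.append(slice(d, None))
        else:
            sl_a.append(slice(-d, None)), sl_b.append(slice(None, d))
    a, b = lev[tuple(sl_a)], lev[tuple(sl_b)]
    valid = m[tuple(sl_a)] & m[tuple(sl_b)]
    return a[valid], b[valid]


def build_glcm(q: QuantizedVolume) -> CoocMatrix:
    """Average of the 13 direction-wise normalized co-occurrence matrices.

    Each directional matrix counts symmetric pairs (both orders) of
    within-mask neighbors at distance 1 and is normalized to sum to 1
    before averaging; directions without any valid pair are skipped.
    """
    masked = q.masked_levels
    lo, hi = int(masked.min()), int(masked.max())
    size = hi - lo + 1
    acc = np.zeros((size, size))
    n_dirs = 0
    for offset in DIRECTIONS_13:
        a, b = _offset_pairs(q, offset)
        if a.size == 0:
            continue
        counts = np.zeros((size, size))
        np.add.at(counts, (a - lo, b - lo), 1.0)
        np.add.at(counts, (b - lo, a - lo), 1.0)
        acc += counts / counts.sum()
        n_dirs += 1
    if n_dirs == 0:
        raise DegenerateRegionError("no within-mask neighbor pair in any direction")
    return CoocMatrix(matrix=acc / n_dirs, min_level=lo)


def glcm_features(m: CoocMatrix) -> dict[str, float]:
    """The 10 co-occurrence indices of a normalized GLCM."""
    p = m.matrix
    size = p.shape[0]
    i = np.arange(size, dtype=float)[:, None] + 1.0  # 1-based, offset cancels
    j = i.T
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    diff = i - j
    nonzero = p > 0
    if var_i > 0 and var_j > 0:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    else:
        correlation = float("nan")
    return {
        "GLCM_variance": var_i,
        "GLCM_energy": float((p**2).sum()),
        "GLCM_entropy": float(-(p[nonzero] * np.log2(p[nonzero])).sum()),
        "GLCM_correlation": correlation,
        "GLCM_dissimilarity": float((np.abs(diff) * p).sum()),
        "GLCM_contrast": float((diff**2 * p).sum()),
        "GLCM_homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
        "GLCM_IDM": float((p / (1.0 + diff**2)).sum()),
        "GLCM_cluster_shade": float(((i + j - mu_i - mu_j) ** 3 * p).sum()),
        "GLCM_cluster_tendency": float(((i + j - mu_i - mu_j) ** 2 * p).sum()),
    }


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def build_glszm(q: QuantizedVolume, connectivity: int = 26) -> SizeZoneMatrix:
    """Size-zone matrix: maximal same-level connected components by size."""
    struct = _STRUCT_26 if connectivity == 26 else _STRUCT_6
    masked = q.masked_levels
    lo, hi = int(masked.min()), int(masked.max())
    present = np.arange(lo, hi + 1)
    zone_sizes: dict[int, list[int]] = {}
    max_size = 1
    for level in present:
        region = (q.levels == level) & q.mask
        if not region.any():
            continue
        labels, n_comp = ndimage.label(region, structure=struct)
        sizes = np.bincount(labels.ravel())[1:]
        zone_sizes[level] = sizes.tolist()
        max_size = max(max_size, int(sizes.max()))
    matrix = np.zeros((hi - lo + 1, max_size))
    for level, sizes in zone_sizes.items():
        for s in sizes:
            matrix[level - lo, s - 1] += 1
    return SizeZoneMatrix(
        matrix=matrix,
        levels=present + 1,  # 1-based formula levels
        total_zones=int(matrix.sum()),
        total_voxels=int(masked.size),
    )


def glszm_features(
    q: QuantizedVolume, connectivity: int = 26
) -> tuple[SizeZoneMatrix, dict[str, float]]:
    """The 11 size-zone indices; returns the matrix alongside."""
    szm = build_glszm(q, connectivity)
    P = szm.matrix
    n = szm.total_zones
    i = szm.levels.astype(float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    feats = {
        "GLSZM_SZE": float((P / j**2).sum() / n),
        "GLSZM_LZE": float((P * j**2).sum() / n),
        "GLSZM_LGZE": float((P / i**2).sum() / n),
        "GLSZM_HGZE": float((P * i**2).sum() / n),
        "GLSZM_SZLGE": float((P / (i**2 * j**2)).sum() / n),
        "GLSZM_LZLGE": float((P * j**2 / i**2).sum() / n),
        "GLSZM_SZHGE": float((P * i**2 / j**2).sum() / n),
        "GLSZM_LZHGE": float((P * i**2 * j**2).sum() / n),
        "GLSZM_ZP": float(n / szm.total_voxels),
        "GLSZM_GLNUz": float((P.sum(axis=1) ** 2).sum() / n),
        "GLSZM_ZLNU": float((P.sum(axis=0) ** 2).sum() / n),
    }
    return szm, feats


def build_gldm(q: QuantizedVolume) -> NeighborhoodDifferenceTable:
    """Neighborhood gray-tone difference table over masked 26-neighbors.

    For every masked voxel with at least one masked 26-neighbor, the
    absolute difference between its level and the mean level of those
    neighbors is accumulated per gray level. Voxels without masked
    neighbors are excluded from both p and s.
    """
    lev = np.where(q.mask, q.levels, 0).astype(float)
    m = q.mask.astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neighbor_sum = ndimage.convolve(lev, kernel, mode="constant", cval=0.0)
    neighbor_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    valid = q.mask & (neighbor_cnt > 0)
    if not valid.any():
        raise DegenerateRegionError("no masked voxel has a masked neighbor")
    diffs = np.abs(q.levels[valid] - neighbor_sum[valid] / neighbor_cnt[valid])
    levels = q.levels[valid]
    lo = levels.min()
    n_counts = np.bincount(levels - lo)
    s_sums = np.bincount(levels - lo, weights=diffs)
    present = n_counts > 0
    level_values = np.arange(lo, levels.max() + 1)[present] + 1  # 1-based
    n_valid = int(valid.sum())
    return NeighborhoodDifferenceTable(
        levels=level_values.astype(float),
        p=n_counts[present] / n_valid,
        s=s_sums[present],
        n_valid=n_valid,
    )


def gldm_features(
    q: QuantizedVolume,
) -> tuple[NeighborhoodDifferenceTable, dict[str, float]]:
    """Coarseness, contrast, busyness, complexity, strength."""
    table = build_gldm(q)
    i = table.levels
    p, s = table.p, table.s
    n = table.n_valid
    ng = i.size

    ps = float((p * s).sum())
    coarseness = min(1.0 / ps, COARSENESS_MAX) if ps > 0 else COARSENESS_MAX

    if ng > 1:
        di = i[:, None] - i[None, :]
        contrast = float(
            (p[:, None] * p[None, :] * di**2).sum() / (ng * (ng - 1)) * (s.sum() / n)
        )
        ipi = i * p
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else float("nan")
        pspj = p[:, None] * s[:, None] + p[None, :] * s[None, :]
        complexity = float(
            (np.abs(di) * pspj / (p[:, None] + p[None, :])).sum() / n
        )
        s_total = float(s.sum())
        strength = (
            float(((p[:, None] + p[None, :]) * di**2).sum() / s_total)
            if s_total > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = float("nan")
        complexity = 0.0
        strength = 0.0

    feats = {
        "GLDM_coarseness": coarseness,
        "GLDM_contrast": contrast,
        "GLDM_busyness": busyness,
        "GLDM_complexity": complexity,
        "GLDM_strength": strength,
    }
    return table, feats
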