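"""Texture count matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) on discretized regions.

All matrices are computed in 3-D on the region's bounding box.  Gray
levels are the discretization bin numbers; empty bins are dropped, with
the surviving bin numbers kept as the level values entering the feature
formulas.  Conventions:

* GLCM — 13 unique distance-1 directions, each pair counted in both
  orders (symmetric), all directions summed into one matrix.
* GLRLM — maximal runs of equal level along the same 13 directions;
  out-of-region voxels break runs.
* GLSZM — 26-connected iso-level zones.
* GLDM — dependence of a voxel = 1 + number of its 26-neighbours inside
  the region with the same level (alpha = 0; the centre voxel counts
  itself, so dependence >= 1).
* NGTDM — per level, the count n_i of region voxels having at least one
  in-region 26-neighbour and the summed absolute difference s_i between
  the level and the mean level of those neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..core_io import Mask

__all__ = ["TextureMatrices", "compute_matrices", "DIRECTIONS_13", "OFFSETS_26"]

#: The 13 unique 3-D directions at Chebyshev distance 1 (half of the 26
#: neighbour offsets, first non-zero component positive).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class TextureMatrices:
    """Count matrices of one (region, discretization) pair.

    ``level_values`` are the surviving discretization bin numbers; every
    matrix row corresponds to the same entry of ``level_values``.
    """

    level_values: np.ndarray          # (L,)
    glcm: np.ndarray                  # (L, L) symmetric counts
    glrlm: np.ndarray                 # (L, Rmax) counts, run length r = column + 1
    glszm: np.ndarray                 # (L, K) counts over distinct zone sizes
    glszm_sizes: np.ndarray           # (K,) the distinct zone sizes
    gldm: np.ndarray                  # (L, D) counts, dependence j = column + 1
    ngtdm_n: np.ndarray               # (L,) voxel counts with a valid neighbourhood
    ngtdm_s: np.ndarray               # (L,) summed |level - neighbourhood mean|
    n_voxels: int

    def __post_init__(self) -> None:
        assert (self.glcm >= 0).all() and np.allclose(self.glcm, self.glcm.T)


def _shift_pairs(shape, offset):
    """Index slices (a, b) so that arr[a] and arr[b] are offset-separated voxels."""
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


def _glcm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    mat = np.zeros((n_levels + 1, n_levels + 1), dtype=np.int64)
    for off in DIRECTIONS_13:
        sa, sb = _shift_pairs(levels.shape, off)
        a, b = levels[sa], levels[sb]
        valid = (a > 0) & (b > 0)
        np.add.at(mat, (a[valid], b[valid]), 1)
    mat = mat + mat.T  # count both orders -> symmetric
    return mat[1:, 1:]


def _glrlm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    shape = levels.shape
    idx = np.indices(shape).reshape(3, -1)
    flat = levels.reshape(-1)
    counts: dict[tuple[int, int], int] = {}
    max_len = 1
    for d in DIRECTIONS_13:
        axis = next(i for i in range(3) if d[i] != 0)
        t = idx[axis]
        line_keys = [idx[i] - t * d[i] for i in range(3) if i != axis]
        order = np.lexsort((t, *line_keys))
        seq = flat[order]
        key_sorted = np.stack([k[order] for k in line_keys], axis=0)
        new_line = np.ones(seq.size, dtype=bool)
        if seq.size > 1:
            new_line[1:] = (np.diff(key_sorted, axis=1) != 0).any(axis=0)
        change = new_line.copy()
        change[1:] |= seq[1:] != seq[:-1]
        run_id = np.cumsum(change) - 1
        lengths = np.bincount(run_id)
        run_levels = seq[change]
        keep = run_levels > 0
        for lev, ln in zip(run_levels[keep], lengths[keep]):
            counts[(int(lev), int(ln))] = counts.get((int(lev), int(ln)), 0) + 1
            max_len = max(max_len, int(ln))
    mat = np.zeros((n_levels + 1, max_len), dtype=np.int64)
    for (lev, ln), c in counts.items():
        mat[lev, ln - 1] = c
    return mat[1:, :]


def _glszm(levels: np.ndarray, n_levels: int):
    sizes_per_level: list[np.ndarray] = []
    all_sizes: set[int] = set()
    for lev in range(1, n_levels + 1):
        binary = levels == lev
        if not binary.any():
            sizes_per_level.append(np.zeros(0, dtype=np.int64))
            continue
        lab, n = ndimage.label(binary, structure=_STRUCT_26)
        sz = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1)).astype(np.int64)
        sizes_per_level.append(sz)
        all_sizes.update(int(s) for s in sz)
    size_values = np.array(sorted(all_sizes) or [1], dtype=np.int64)
    mat = np.zeros((n_levels, size_values.size), dtype=np.int64)
    lookup = {int(s): k for k, s in enumerate(size_values)}
    for row, sz in enumerate(sizes_per_level):
        for s in sz:
            mat[row, lookup[int(s)]] += 1
    return mat, size_values


def _gldm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    inside = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sa, sb = _shift_pairs(levels.shape, off)
        same = np.zeros(levels.shape, dtype=bool)
        same[sa] = (levels[sa] == levels[sb]) & (levels[sb] > 0)
        dep += same & inside
    # centre voxel counts itself: dependence >= 1 always
    j = (dep + 1)[inside]
    i = levels[inside]
    max_dep = int(j.max())
    mat = np.zeros((n_levels + 1, max_dep), dtype=np.int64)
    np.add.at(mat, (i, j - 1), 1)
    return mat[1:, :]


def _ngtdm(levels: np.ndarray, n_levels: int):
    inside = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sa, sb = _shift_pairs(levels.shape, off)
        contrib = np.zeros(levels.shape, dtype=np.float64)
        cnt = np.zeros(levels.shape, dtype=np.int64)
        contrib[sa] = np.where(levels[sb] > 0, levels[sb], 0.0)
        cnt[sa] = levels[sb] > 0
        nb_sum += contrib
        nb_cnt += cnt
    valid = inside & (nb_cnt > 0)
    diff = np.zeros(levels.shape, dtype=np.float64)
    diff[valid] = np.abs(levels[valid] - nb_sum[valid] / nb_cnt[valid])
    n_i = np.zeros(n_levels + 1, dtype=np.int64)
    s_i = np.zeros(n_levels + 1, dtype=np.float64)
    np.add.at(n_i, levels[valid], 1)
    np.add.at(s_i, levels[valid], diff[valid])
    return n_i[1:], s_i[1:]


def compute_matrices(levels: np.ndarray, region: Mask | np.ndarray) -> TextureMatrices:
    """Compute all five texture matrices from a discretized level lattice.

    ``levels`` must be 0 outside the region (as produced by
    :func:`~aslsubvol.radiomics.discretize.discretize`); single-voxel
    regions yield well-defined degenerate matrices.
    """
    region_data = region.data if isinstance(region, Mask) else np.asarray(region, dtype=bool)
    levels = np.where(region_data, levels, 0)
    if not (levels > 0).any():
        raise ValueError("region is empty")

    # crop to the region bounding box for speed
    coords = np.argwhere(levels > 0)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    sub = levels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

    n_levels = int(sub.max())
    glcm_full = _glcm(sub, n_levels)
    glrlm_full = _glrlm(sub, n_levels)
    glszm_full, size_values = _glszm(sub, n_levels)
    gldm_full = _gldm(sub, n_levels)
    n_i, s_i = _ngtdm(sub, n_levels)

    present = np.array(
        sorted(int(v) for v in np.unique(sub) if v > 0), dtype=np.int64
    )
    keep = present - 1
    return TextureMatrices(
        level_values=present,
        glcm=glcm_full[np.ix_(keep, keep)],
        glrlm=glrlm_full[keep, :],
        glszm=glszm_full[keep, :],
        glszm_sizes=size_values,
        gldm=gldm_full[keep, :],
        ngtdm_n=n_i[keep],
        ngtdm_s=s_i[keep],
        n_voxels=int((sub > 0).sum()),
    )
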