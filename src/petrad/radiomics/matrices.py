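"""3D texture-matrix builders.

Six families are computed from a gray-level volume (levels 1..Ng inside the
mask, 0 outside):

- GLCM: symmetric co-occurrence counts of level pairs at Chebyshev
  distance 1, over the 13 unique 3D direction vectors.
- GLRLM: counts of maximal runs of equal level per direction.
- GLSZM: sizes of 26-connected zones of equal level.
- GLDZM: the same zones, indexed by their minimum city-block distance to
  the mask border (border voxels have distance 1).
- NGLDM: per center voxel of level i, the dependence count j = 1 + number
  of neighbors within Chebyshev distance delta whose level differs by at
  most alpha.
- NGTDM: per level i, the summed absolute difference s_i between each
  voxel's level and the mean level of its in-mask neighbors, with
  occurrence counts n_i.

GLCM and GLRLM are directional; they can be merged (counts pooled over the
13 directions) or kept per direction for feature averaging.  The other four
families are direction-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from .discretize import BinnedVolume

__all__ = [
    "DIRECTIONS_3D",
    "TextureMatrix",
    "glcm",
    "glcm_matrices",
    "glrlm",
    "glrlm_matrices",
    "glszm",
    "gldzm",
    "ngldm",
    "ngtdm",
]

#: the 13 unique 3D direction vectors at Chebyshev distance 1 (one per
#: +/- pair; the first nonzero component is positive)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0) and d > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


@dataclass
class TextureMatrix:
    """2D count matrix of one family.

    ``counts[i-1, j-1]`` counts occurrences of (level i, second-axis value
    j), where the second axis is the co-occurring level (GLCM), run length
    (GLRLM), zone size (GLSZM), zone distance (GLDZM) or dependence count
    (NGLDM).  For NGTDM, ``counts[i-1, 0]`` holds the occurrence count n_i
    and ``s[i-1]`` the summed neighborhood difference.

    ``Nz`` is the matrix total (sum of counts); ``n_voxels`` the number of
    in-mask voxels the matrix was built from.
    """

    family: str
    counts: np.ndarray
    n_levels: int
    n_voxels: int
    n_directions: int = 1
    s: np.ndarray | None = field(default=None)

    @property
    def Nz(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        total = self.Nz
        if total <= 0:
            raise ValueError(f"empty {self.family} matrix (Nz = 0)")
        return self.counts / total


def _offset_slices(shape, d):
    """Slice pair (sa, sb) such that arr[sa] and arr[sb] are the aligned
    views of voxel v and voxel v + d."""
    sa, sb = [], []
    for dim, delta in zip(shape, d):
        if delta >= 0:
            sa.append(slice(0, dim - delta))
            sb.append(slice(delta, dim))
        else:
            sa.append(slice(-delta, dim))
            sb.append(slice(0, dim + delta))
    return tuple(sa), tuple(sb)


def _merge(mats: list[TextureMatrix], family: str) -> TextureMatrix:
    width = max(m.counts.shape[1] for m in mats)
    total = np.zeros((mats[0].n_levels, width))
    for m in mats:
        total[:, : m.counts.shape[1]] += m.counts
    return TextureMatrix(
        family=family,
        counts=total,
        n_levels=mats[0].n_levels,
        n_voxels=mats[0].n_voxels,
        n_directions=len(mats),
    )


# ---------------------------------------------------------------- GLCM

def glcm_matrices(binned: BinnedVolume) -> list[TextureMatrix]:
    """One symmetric co-occurrence matrix per 3D direction."""
    lev = binned.levels
    ng = binned.n_bins
    nvox = int((lev > 0).sum())
    out = []
    for d in DIRECTIONS_3D:
        sa, sb = _offset_slices(lev.shape, d)
        a, b = lev[sa], lev[sb]
        valid = (a > 0) & (b > 0)
        av, bv = a[valid] - 1, b[valid] - 1
        m = np.bincount(av * ng + bv, minlength=ng * ng).reshape(ng, ng).astype(float)
        m = m + m.T  # symmetric: each pair counted in both orientations
        out.append(TextureMatrix("glcm", m, ng, nvox))
    return out


def glcm(binned: BinnedVolume, mask=None, config=None) -> TextureMatrix:
    """Co-occurrence matrix pooled (merged) over the 13 directions."""
    return _merge(glcm_matrices(binned), "glcm")


# ---------------------------------------------------------------- GLRLM

def _runs_one_direction(lev: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Start levels and lengths of all maximal runs along direction d."""
    shape = lev.shape
    sa, sb = _offset_slices(shape, d)
    cont = np.zeros(shape, dtype=bool)  # voxel continues its run at v + d
    a, b = lev[sa], lev[sb]
    cont[sa] = (a > 0) & (a == b)
    start = lev > 0
    prev = np.zeros(shape, dtype=bool)  # voxel is continued from v - d
    prev[sb] = cont[sa]
    start &= ~prev

    flat_lev = lev.ravel()
    flat_cont = cont.ravel()
    strides = (shape[1] * shape[2], shape[2], 1)
    step = d[0] * strides[0] + d[1] * strides[1] + d[2] * strides[2]

    idx = np.flatnonzero(start.ravel())
    lengths = np.ones(idx.size, dtype=np.int64)
    pos = idx.copy()
    active = np.arange(idx.size)
    while active.size:
        cont_now = flat_cont[pos[active]]
        active = active[cont_now]
        pos[active] += step
        lengths[active] += 1
    return flat_lev[idx], lengths


def glrlm_matrices(binned: BinnedVolume) -> list[TextureMatrix]:
    """One run-length matrix per 3D direction (rows: level, cols: length)."""
    lev = binned.levels
    ng = binned.n_bins
    nvox = int((lev > 0).sum())
    out = []
    for d in DIRECTIONS_3D:
        start_levels, lengths = _runs_one_direction(lev, d)
        width = int(lengths.max()) if lengths.size else 1
        m = np.zeros((ng, width))
        np.add.at(m, (start_levels - 1, lengths - 1), 1.0)
        out.append(TextureMatrix("glrlm", m, ng, nvox))
    return out


def glrlm(binned: BinnedVolume, mask=None, config=None) -> TextureMatrix:
    """Run-length matrix pooled (merged) over the 13 directions."""
    return _merge(glrlm_matrices(binned), "glrlm")


# ------------------------------------------------------- GLSZM / GLDZM

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


def _zones(binned: BinnedVolume):
    """Yield (level, zone_sizes, zone_labels, n_zones) per gray level."""
    lev = binned.levels
    for g in range(1, binned.n_bins + 1):
        where = lev == g
        if not where.any():
            continue
        labels, n = ndimage.label(where, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())[1:]
        yield g, sizes, labels, n


def glszm(binned: BinnedVolume, mask=None, config=None) -> TextureMatrix:
    """Size-zone matrix: 26-connected zones of equal level, by size."""
    ng = binned.n_bins
    nvox = int((binned.levels > 0).sum())
    rows, sizes_all = [], []
    for g, sizes, _, _ in _zones(binned):
        rows.append(np.full(sizes.size, g - 1))
        sizes_all.append(sizes)
    if not rows:
        raise ValueError("empty mask: no zones")
    rows = np.concatenate(rows)
    sizes_all = np.concatenate(sizes_all)
    m = np.zeros((ng, int(sizes_all.max())))
    np.add.at(m, (rows, sizes_all - 1), 1.0)
    return TextureMatrix("glszm", m, ng, nvox)


def _border_distance(mask: np.ndarray) -> np.ndarray:
    """City-block distance to the nearest out-of-mask voxel; the array
    boundary counts as outside, so border voxels get distance 1."""
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return dist[1:-1, 1:-1, 1:-1]


def gldzm(binned: BinnedVolume, mask=None, config=None) -> TextureMatrix:
    """Distance-zone matrix: the GLSZM zones indexed by their minimum
    city-block distance to the mask border."""
    ng = binned.n_bins
    nvox = int((binned.levels > 0).sum())
    dist = _border_distance(binned.mask)
    rows, dists = [], []
    for g, sizes, labels, n in _zones(binned):
        zone_min = ndimage.minimum(dist, labels, index=np.arange(1, n + 1))
        zone_min = np.atleast_1d(zone_min).astype(int)
        rows.append(np.full(zone_min.size, g - 1))
        dists.append(zone_min)
    if not rows:
        raise ValueError("empty mask: no zones")
    rows = np.concatenate(rows)
    dists = np.concatenate(dists)
    m = np.zeros((ng, int(dists.max())))
    np.add.at(m, (rows, dists - 1), 1.0)
    return TextureMatrix("gldzm", m, ng, nvox)


# ------------------------------------------------------- NGLDM / NGTDM

def _neighbor_offsets(delta: int):
    return [
        d
        for d in product(range(-delta, delta + 1), repeat=3)
        if d != (0, 0, 0) and d > (0, 0, 0)
    ]


def ngldm(binned: BinnedVolume, mask=None, config=None, alpha: int = 0, delta: int = 1) -> TextureMatrix:
    """Dependence matrix: P(i, j) counts in-mask voxels of level i having
    j - 1 dependent neighbors (|level difference| <= alpha) within
    Chebyshev distance delta.  Nz equals the in-mask voxel count."""
    if config is not None:
        alpha = getattr(config, "gldm_alpha", alpha)
        delta = getattr(config, "neighborhood_delta", delta)
    lev = binned.levels
    shape = lev.shape
    in_mask = lev > 0
    dep = np.zeros(shape, dtype=np.int32)
    for d in _neighbor_offsets(delta):
        sa, sb = _offset_slices(shape, d)
        a, b = lev[sa], lev[sb]
        close = (a > 0) & (b > 0) & (np.abs(a.astype(int) - b.astype(int)) <= alpha)
        dep[sa] += close
        dep[sb] += close
    max_j = int(dep[in_mask].max()) + 1 if in_mask.any() else 1
    ng = binned.n_bins
    m = np.zeros((ng, max_j))
    np.add.at(m, (lev[in_mask] - 1, dep[in_mask]), 1.0)  # column j = k + 1
    return TextureMatrix("ngldm", m, ng, int(in_mask.sum()))


def ngtdm(binned: BinnedVolume, mask=None, config=None, delta: int = 1) -> TextureMatrix:
    """Neighborhood gray-tone difference matrix: per level i, the sum s_i of
    |level - mean neighbor level| over voxels of level i, with occurrence
    counts n_i.  Voxels with no in-mask neighbor are excluded."""
    if config is not None:
        delta = getattr(config, "neighborhood_delta", delta)
    lev = binned.levels
    shape = lev.shape
    in_mask = lev > 0
    nb_sum = np.zeros(shape)
    nb_cnt = np.zeros(shape, dtype=np.int32)
    for d in _neighbor_offsets(delta):
        sa, sb = _offset_slices(shape, d)
        a, b = lev[sa], lev[sb]
        valid = (a > 0) & (b > 0)
        nb_sum[sa] += np.where(valid, b, 0)
        nb_cnt[sa] += valid
        nb_sum[sb] += np.where(valid, a, 0)
        nb_cnt[sb] += valid
    has_nb = in_mask & (nb_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.abs(lev - nb_sum / np.maximum(nb_cnt, 1))
    ng = binned.n_bins
    n_i = np.bincount(lev[has_nb] - 1, minlength=ng).astype(float)
    s_i = np.bincount(lev[has_nb] - 1, weights=diff[has_nb], minlength=ng)
    return TextureMatrix(
        "ngtdm", n_i.reshape(-1, 1), ng, int(in_mask.sum()), s=s_i
    )
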