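"""Texture features computed from the family matrices.

All entropies use base-2 logarithms with the convention 0*log(0) = 0.
Degenerate inputs (a single occupied gray level, zero variance) yield NaN
for the features whose definition divides by the vanishing quantity; NaNs
are propagated, never silently replaced.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrix

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldzm_features",
    "ngldm_features",
    "ngldm_feature_dependence_count_nonuniformity",
    "ngldm_feature_low_dep_low_gray_emphasis",
    "ngtdm_features",
    "COARSENESS_CAP",
]

#: upper cap for NGTDM coarseness when the denominator vanishes
COARSENESS_CAP = 1e6


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    return float(-_xlog2(p).sum())


# ---------------------------------------------------------------- GLCM

def glcm_features(mat: TextureMatrix) -> dict[str, float]:
    """25 co-occurrence features on the normalized symmetric matrix."""
    p = mat.normalized()
    ng = mat.n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # row marginal (= column marginal by symmetry)

    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())

    # diagonal (|i-j| = k) and cross-diagonal (i+j = m) distributions
    k = np.arange(ng)
    p_dk = np.array([p[np.abs(ii - jj) == kk].sum() for kk in k])
    m = np.arange(2, 2 * ng + 1)
    p_sm = np.array([p[(ii + jj) == mm].sum() for mm in m])

    da = float((k * p_dk).sum())
    sa = float((m * p_sm).sum())

    feats: dict[str, float] = {}
    feats["joint_maximum"] = float(p.max())
    feats["joint_average"] = mu
    feats["joint_variance"] = var
    hxy = _entropy(p)
    feats["joint_entropy"] = hxy
    feats["difference_average"] = da
    feats["difference_variance"] = float(((k - da) ** 2 * p_dk).sum())
    feats["difference_entropy"] = _entropy(p_dk)
    feats["sum_average"] = sa
    feats["sum_variance"] = float(((m - sa) ** 2 * p_sm).sum())
    feats["sum_entropy"] = _entropy(p_sm)
    feats["angular_second_moment"] = float((p**2).sum())
    feats["contrast"] = float((k**2 * p_dk).sum())
    feats["dissimilarity"] = da
    feats["inverse_difference"] = float((p_dk / (1 + k)).sum())
    feats["inverse_difference_normalised"] = float((p_dk / (1 + k / ng)).sum())
    feats["inverse_difference_moment"] = float((p_dk / (1 + k**2)).sum())
    feats["inverse_difference_moment_normalised"] = float((p_dk / (1 + (k / ng) ** 2)).sum())
    inv_var = (p_dk[1:] / k[1:] ** 2).sum()
    feats["inverse_variance"] = float(inv_var)
    autoc = float((ii * jj * p).sum())
    feats["correlation"] = (autoc - mu**2) / var if var > 0 else float("nan")
    feats["autocorrelation"] = autoc
    dev = ii + jj - 2 * mu
    feats["cluster_tendency"] = float((dev**2 * p).sum())
    feats["cluster_shade"] = float((dev**3 * p).sum())
    feats["cluster_prominence"] = float((dev**4 * p).sum())

    hx = _entropy(pi)
    outer = np.outer(pi, pi)
    hxy1 = float(-(p * np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0)).sum())
    hxy2 = _entropy(outer)
    feats["information_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else float("nan")
    feats["information_correlation_2"] = (
        float(np.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    )
    return feats


# ------------------------------------- shared run/zone/dependence core

def _distribution_features(mat: TextureMatrix, names: dict[str, str],
                           percentage_denominator: float) -> dict[str, float]:
    """The 16-feature emphasis / non-uniformity / variance / entropy core
    shared by GLRLM, GLSZM, GLDZM and NGLDM (with family-specific names).

    ``names`` maps the generic keys to family feature names; the second
    matrix axis (run length, zone size, zone distance or dependence count)
    is called j here.
    """
    counts = mat.counts
    nz = mat.Nz
    if nz <= 0:
        raise ValueError(f"empty {mat.family} matrix")
    p = counts / nz
    ni, nj = counts.shape
    i = np.arange(1, ni + 1)
    j = np.arange(1, nj + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    ri = counts.sum(axis=1)  # level marginal
    rj = counts.sum(axis=0)  # j marginal
    pi = ri / nz
    pj = rj / nz

    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())

    f: dict[str, float] = {}
    f[names["low_j"]] = float((p / jj**2).sum())
    f[names["high_j"]] = float((p * jj**2).sum())
    f[names["low_g"]] = float((p / ii**2).sum())
    f[names["high_g"]] = float((p * ii**2).sum())
    f[names["low_j_low_g"]] = float((p / (ii**2 * jj**2)).sum())
    f[names["low_j_high_g"]] = float((p * ii**2 / jj**2).sum())
    f[names["high_j_low_g"]] = float((p * jj**2 / ii**2).sum())
    f[names["high_j_high_g"]] = float((p * ii**2 * jj**2).sum())
    f[names["gln"]] = float((ri**2).sum() / nz)
    f[names["gln_norm"]] = float((ri**2).sum() / nz**2)
    f[names["jn"]] = float((rj**2).sum() / nz)
    f[names["jn_norm"]] = float((rj**2).sum() / nz**2)
    f[names["percentage"]] = float(nz / percentage_denominator)
    f[names["g_var"]] = float((pi * (i - mu_i) ** 2).sum())
    f[names["j_var"]] = float((pj * (j - mu_j) ** 2).sum())
    f[names["entropy"]] = _entropy(p)
    if "energy" in names:
        f[names["energy"]] = float((p**2).sum())
    return f


_GLRLM_NAMES = {
    "low_j": "short_run_emphasis",
    "high_j": "long_run_emphasis",
    "low_g": "low_grey_level_run_emphasis",
    "high_g": "high_grey_level_run_emphasis",
    "low_j_low_g": "short_run_low_grey_level_emphasis",
    "low_j_high_g": "short_run_high_grey_level_emphasis",
    "high_j_low_g": "long_run_low_grey_level_emphasis",
    "high_j_high_g": "long_run_high_grey_level_emphasis",
    "gln": "grey_level_non_uniformity",
    "gln_norm": "grey_level_non_uniformity_normalised",
    "jn": "run_length_non_uniformity",
    "jn_norm": "run_length_non_uniformity_normalised",
    "percentage": "run_percentage",
    "g_var": "grey_level_variance",
    "j_var": "run_length_variance",
    "entropy": "run_entropy",
}

_GLSZM_NAMES = {
    "low_j": "small_zone_emphasis",
    "high_j": "large_zone_emphasis",
    "low_g": "low_grey_level_zone_emphasis",
    "high_g": "high_grey_level_zone_emphasis",
    "low_j_low_g": "small_zone_low_grey_level_emphasis",
    "low_j_high_g": "small_zone_high_grey_level_emphasis",
    "high_j_low_g": "large_zone_low_grey_level_emphasis",
    "high_j_high_g": "large_zone_high_grey_level_emphasis",
    "gln": "grey_level_non_uniformity",
    "gln_norm": "grey_level_non_uniformity_normalised",
    "jn": "zone_size_non_uniformity",
    "jn_norm": "zone_size_non_uniformity_normalised",
    "percentage": "zone_percentage",
    "g_var": "grey_level_variance",
    "j_var": "zone_size_variance",
    "entropy": "zone_size_entropy",
}

_GLDZM_NAMES = {
    "low_j": "small_distance_emphasis",
    "high_j": "large_distance_emphasis",
    "low_g": "low_grey_level_zone_emphasis",
    "high_g": "high_grey_level_zone_emphasis",
    "low_j_low_g": "small_distance_low_grey_level_emphasis",
    "low_j_high_g": "small_distance_high_grey_level_emphasis",
    "high_j_low_g": "large_distance_low_grey_level_emphasis",
    "high_j_high_g": "large_distance_high_grey_level_emphasis",
    "gln": "grey_level_non_uniformity",
    "gln_norm": "grey_level_non_uniformity_normalised",
    "jn": "zone_distance_non_uniformity",
    "jn_norm": "zone_distance_non_uniformity_normalised",
    "percentage": "zone_percentage",
    "g_var": "grey_level_variance",
    "j_var": "zone_distance_variance",
    "entropy": "zone_distance_entropy",
}

_NGLDM_NAMES = {
    "low_j": "low_dependence_emphasis",
    "high_j": "high_dependence_emphasis",
    "low_g": "low_grey_level_count_emphasis",
    "high_g": "high_grey_level_count_emphasis",
    "low_j_low_g": "low_dependence_low_grey_level_emphasis",
    "low_j_high_g": "low_dependence_high_grey_level_emphasis",
    "high_j_low_g": "high_dependence_low_grey_level_emphasis",
    "high_j_high_g": "high_dependence_high_grey_level_emphasis",
    "gln": "grey_level_non_uniformity",
    "gln_norm": "grey_level_non_uniformity_normalised",
    "jn": "dependence_count_non_uniformity",
    "jn_norm": "dependence_count_non_uniformity_normalised",
    "percentage": "dependence_count_percentage",
    "g_var": "grey_level_variance",
    "j_var": "dependence_count_variance",
    "entropy": "dependence_count_entropy",
    "energy": "dependence_count_energy",
}


def glrlm_features(mat: TextureMatrix) -> dict[str, float]:
    """16 run-length features; run percentage uses Nv per direction (the
    merged matrix divides by n_directions * Nv)."""
    denom = mat.n_voxels * mat.n_directions
    return _distribution_features(mat, _GLRLM_NAMES, denom)


def glszm_features(mat: TextureMatrix) -> dict[str, float]:
    return _distribution_features(mat, _GLSZM_NAMES, mat.n_voxels)


def gldzm_features(mat: TextureMatrix) -> dict[str, float]:
    return _distribution_features(mat, _GLDZM_NAMES, mat.n_voxels)


def ngldm_features(mat: TextureMatrix) -> dict[str, float]:
    return _distribution_features(mat, _NGLDM_NAMES, mat.n_voxels)


def ngldm_feature_dependence_count_nonuniformity(mat: TextureMatrix) -> float:
    """DN = sum_j (sum_i P(i,j))^2 / Nz.  Low values indicate homogeneous
    dependence structure across the volume."""
    if mat.Nz <= 0:
        raise ValueError("empty dependence matrix")
    col = mat.counts.sum(axis=0)
    return float((col**2).sum() / mat.Nz)


def ngldm_feature_low_dep_low_gray_emphasis(mat: TextureMatrix) -> float:
    """LDLGLE = (sum_ij P(i,j) / (i^2 j^2)) / Nz: joint emphasis of small
    dependence counts and low gray levels."""
    if mat.Nz <= 0:
        raise ValueError("empty dependence matrix")
    ni, nj = mat.counts.shape
    i = np.arange(1, ni + 1)[:, None]
    j = np.arange(1, nj + 1)[None, :]
    return float((mat.counts / (i**2 * j**2)).sum() / mat.Nz)


# ---------------------------------------------------------------- NGTDM

def ngtdm_features(mat: TextureMatrix) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength."""
    if mat.s is None:
        raise ValueError("NGTDM matrix required (missing s_i)")
    n_i = mat.counts[:, 0]
    s_i = mat.s
    nz = n_i.sum()
    if nz <= 0:
        raise ValueError("empty NGTDM")
    p_i = n_i / nz
    i = np.arange(1, mat.n_levels + 1)
    occupied = p_i > 0
    ngp = int(occupied.sum())

    f: dict[str, float] = {}
    denom = float((p_i * s_i).sum())
    f["coarseness"] = min(1.0 / denom, COARSENESS_CAP) if denom > 0 else COARSENESS_CAP

    if ngp > 1:
        io, po = i[occupied], p_i[occupied]
        so = s_i[occupied]
        di = io[:, None] - io[None, :]
        pp = po[:, None] * po[None, :]
        f["contrast"] = float(
            (pp * di**2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nz
        )
        ip = io * po
        busy_den = float(np.abs(ip[:, None] - ip[None, :]).sum())
        f["busyness"] = denom / busy_den if busy_den > 0 else float("nan")
        num = np.abs(di) * (po[:, None] * so[:, None] + po[None, :] * so[None, :]) / (
            po[:, None] + po[None, :]
        )
        f["complexity"] = float(num.sum() / nz)
        s_sum = float(s_i.sum())
        f["strength"] = (
            float(((po[:, None] + po[None, :]) * di**2).sum() / s_sum) if s_sum > 0 else 0.0
        )
    else:
        f["contrast"] = float("nan")
        f["busyness"] = float("nan")
        f["complexity"] = 0.0
        f["strength"] = 0.0
    return f
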