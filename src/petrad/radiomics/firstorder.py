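"""First-order features: morphology, local intensity, intensity
statistics, intensity-histogram statistics and the intensity-volume
histogram (79 features in total).

Conventions
-----------
- Moments are population moments (denominator N); kurtosis is excess
  kurtosis (normal distribution -> 0).
- Percentiles use the linear-interpolation rule (numpy default).
- Morphology is voxel-based: volume = voxel count x voxel volume, surface
  area = exposed-face count weighted by face areas.  On a cohort sharing a
  template mask these are constant across subjects by design (whole-brain
  VOI) and therefore uninformative for selection.
- The intensity-volume histogram works on the fractional intensity
  gamma = (x - min)/(max - min); V_x is the fraction of in-mask volume with
  intensity >= the gamma = x/100 threshold, I_x the intensity threshold
  below which at most x% of the volume lies in the high tail.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from ..grids import VolumeGrid
from .discretize import BinnedVolume, discretize

__all__ = ["first_order_features", "LOCAL_PEAK_RADIUS_MM"]

#: radius of the spherical neighborhood used for intensity peaks (~1 cm^3)
LOCAL_PEAK_RADIUS_MM = 6.2


# ---------------------------------------------------------- morphology

def _surface_area(mask: np.ndarray, voxel_size) -> float:
    vs = np.asarray(voxel_size, dtype=float)
    face_area = [vs[1] * vs[2], vs[0] * vs[2], vs[0] * vs[1]]
    area = 0.0
    padded = np.pad(mask, 1)
    for axis in range(3):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += np.abs(diff).sum() * face_area[axis]
    return float(area)


def _max_diameter(coords_mm: np.ndarray) -> float:
    """Largest pairwise distance between surface voxel centres, via the
    convex hull (falls back to brute force on degenerate point sets)."""
    if len(coords_mm) < 2:
        return 0.0
    pts = coords_mm
    if len(pts) > 10:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def _morphology(volume: VolumeGrid, mask: np.ndarray) -> dict[str, float]:
    vs = np.asarray(volume.voxel_size_mm)
    n = int(mask.sum())
    vol = n * volume.voxel_volume_mm3
    area = _surface_area(mask, vs)

    coords = np.argwhere(mask).astype(float)
    coords_mm = coords * vs
    centroid = coords_mm.mean(axis=0)
    w = volume.data[mask]
    w_total = w.sum()
    wc = (coords_mm * w[:, None]).sum(axis=0) / w_total if w_total > 0 else centroid

    # boundary voxels: at least one 6-neighbor outside the mask
    eroded = ndimage.binary_erosion(mask)
    boundary_mm = np.argwhere(mask & ~eroded).astype(float) * vs

    cov = np.cov(coords_mm.T) if len(coords_mm) > 1 else np.zeros((3, 3))
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    axes = 4.0 * np.sqrt(eig)

    extent_mm = (coords_mm.max(axis=0) - coords_mm.min(axis=0)) + vs
    aabb_vol = float(np.prod(extent_mm))

    f: dict[str, float] = {}
    f["voxel_count"] = float(n)
    f["volume_mm3"] = vol
    f["surface_area_mm2"] = area
    f["surface_to_volume_ratio"] = area / vol
    f["compactness_1"] = vol / (np.sqrt(np.pi) * area**1.5)
    f["compactness_2"] = 36.0 * np.pi * vol**2 / area**3
    f["spherical_disproportion"] = area / (36.0 * np.pi * vol**2) ** (1.0 / 3.0)
    f["sphericity"] = (36.0 * np.pi * vol**2) ** (1.0 / 3.0) / area
    f["asphericity"] = (area**3 / (36.0 * np.pi * vol**2)) ** (1.0 / 3.0) - 1.0
    f["centre_of_mass_shift_mm"] = float(np.linalg.norm(centroid - wc))
    f["max_diameter_mm"] = _max_diameter(boundary_mm)
    f["major_axis_length_mm"] = float(axes[0])
    f["minor_axis_length_mm"] = float(axes[1])
    f["least_axis_length_mm"] = float(axes[2])
    f["elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else float("nan")
    f["flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else float("nan")
    f["volume_density_aabb"] = vol / aabb_vol
    f["integrated_intensity"] = float(w.mean() * vol)
    return f


# ------------------------------------------------------ local intensity

def _sphere_kernel(radius_mm: float, voxel_size) -> np.ndarray:
    vs = np.asarray(voxel_size, dtype=float)
    half = np.maximum(np.floor(radius_mm / vs).astype(int), 0)
    grids = np.ogrid[-half[0]: half[0] + 1, -half[1]: half[1] + 1, -half[2]: half[2] + 1]
    r2 = sum((g * s) ** 2 for g, s in zip(grids, vs))
    return (r2 <= radius_mm**2).astype(float)


def _local_intensity(volume: VolumeGrid, mask: np.ndarray) -> dict[str, float]:
    kernel = _sphere_kernel(LOCAL_PEAK_RADIUS_MM, volume.voxel_size_mm)
    kernel /= kernel.sum()
    means = ndimage.correlate(volume.data, kernel, mode="nearest")
    vals = volume.data[mask]
    at_max = mask & (volume.data == vals.max())
    return {
        "local_intensity_peak": float(means[at_max].max()),
        "global_intensity_peak": float(means[mask].max()),
    }


# ------------------------------------------------- intensity statistics

def _stats(x: np.ndarray, prefix: str = "") -> dict[str, float]:
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    std = float(np.sqrt(var))
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, med, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    in_core = x[(x >= p10) & (x <= p90)]

    f: dict[str, float] = {}
    f["mean"] = mean
    f["variance"] = var
    f["standard_deviation"] = std
    f["skewness"] = m3 / var**1.5 if var > 0 else float("nan")
    f["excess_kurtosis"] = m4 / var**2 - 3.0 if var > 0 else float("nan")
    f["median"] = med
    f["minimum"] = float(x.min())
    f["maximum"] = float(x.max())
    f["range"] = float(x.max() - x.min())
    f["percentile_10"] = p10
    f["percentile_25"] = p25
    f["percentile_75"] = p75
    f["percentile_90"] = p90
    f["interquartile_range"] = p75 - p25
    f["mean_absolute_deviation"] = float(np.abs(x - mean).mean())
    f["robust_mean_absolute_deviation"] = (
        float(np.abs(in_core - in_core.mean()).mean()) if in_core.size else float("nan")
    )
    f["median_absolute_deviation"] = float(np.abs(x - med).mean())
    f["coefficient_of_variation"] = std / mean if mean != 0 else float("nan")
    qsum = p75 + p25
    f["quartile_coefficient_of_dispersion"] = (p75 - p25) / qsum if qsum != 0 else float("nan")
    f["energy"] = float((x**2).sum())
    f["root_mean_square"] = float(np.sqrt((x**2).mean()))
    f["sum"] = float(x.sum())
    return {prefix + k: v for k, v in f.items()}


# ------------------------------------------------- histogram statistics

def _histogram_stats(binned: BinnedVolume) -> dict[str, float]:
    lev = binned.levels[binned.mask].astype(float)
    counts = np.bincount(binned.levels[binned.mask], minlength=binned.n_bins + 1)[1:]
    p = counts / counts.sum()

    f = _stats(lev)
    f.pop("energy")
    f.pop("root_mean_square")
    f.pop("sum")
    # mode: lowest level with the maximal count
    f["mode"] = float(np.argmax(counts) + 1)
    f["entropy"] = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    f["uniformity"] = float((p**2).sum())

    # histogram gradient: central differences, one-sided at the edges
    grad = np.gradient(counts.astype(float))
    f["max_histogram_gradient"] = float(grad.max())
    f["max_histogram_gradient_level"] = float(np.argmax(grad) + 1)
    f["min_histogram_gradient"] = float(grad.min())
    f["min_histogram_gradient_level"] = float(np.argmin(grad) + 1)
    return {"ih_" + k: v for k, v in f.items()}


# --------------------------------------------- intensity-volume histogram

def _ivh(x: np.ndarray) -> dict[str, float]:
    lo, hi = float(x.min()), float(x.max())
    f: dict[str, float] = {}
    if hi == lo:
        for q in (10, 25, 50, 75, 90):
            f[f"ivh_volume_at_intensity_{q}"] = 1.0
            f[f"ivh_intensity_at_volume_{q}"] = lo
        f["ivh_auc"] = 1.0
        return f
    gamma = (x - lo) / (hi - lo)
    for q in (10, 25, 50, 75, 90):
        f[f"ivh_volume_at_intensity_{q}"] = float((gamma >= q / 100.0).mean())
    for q in (10, 25, 50, 75, 90):
        # smallest intensity such that at most q% of the volume is above it
        f[f"ivh_intensity_at_volume_{q}"] = float(np.percentile(x, 100 - q))
    grid = np.linspace(0.0, 1.0, 1001)
    nu = (gamma[None, :] >= grid[:, None]).mean(axis=1)
    f["ivh_auc"] = float(np.trapezoid(nu, grid))
    return f


def first_order_features(
    volume: VolumeGrid, mask: np.ndarray, binned: BinnedVolume | None = None, n_bins: int = 32
) -> dict[str, float]:
    """All 79 first-order features as an ordered name -> value mapping."""
    if not mask.any():
        raise ValueError("empty mask")
    if binned is None:
        binned = discretize(volume, mask, n_bins)
    x = volume.data[mask].astype(float)

    feats: dict[str, float] = {}
    feats.update({"morph_" + k: v for k, v in _morphology(volume, mask).items()})
    feats.update(_local_intensity(volume, mask))
    feats.update({"stat_" + k: v for k, v in _stats(x).items()})
    feats.update(_histogram_stats(binned))
    feats.update(_ivh(x))
    return {"firstorder." + k: v for k, v in feats.items()}
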