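"""Single-subject versus control-group voxel-wise statistics.

One patient volume is compared with a set of control volumes by an
ordinary-least-squares fit at every in-mask voxel of intensity on
[intercept, patient indicator, age].  The t statistic of the patient
indicator (negative = hypometabolism when the patient is coded +1) is
thresholded at an uncorrected p and filtered by cluster extent: only
connected components with strictly more than ``min_extent`` voxels are
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .grids import VolumeGrid

__all__ = ["TMap", "Cluster", "ClusterReport", "voxelwise_glm_t", "extract_clusters"]


@dataclass
class TMap:
    """Voxel-wise t and two-sided p maps; values are defined only inside
    the analysis mask (NaN outside)."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]
    """Boolean map of voxels whose residual variance was zero (t forced to 0)."""


@dataclass(frozen=True)
class Cluster:
    voxel_count: int
    peak_t: float
    peak_coordinate: tuple[int, int, int]
    centroid: tuple[float, float, float]


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    threshold_p: float
    min_extent: int

    def __len__(self) -> int:
        return len(self.clusters)


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def voxelwise_glm_t(
    patient: VolumeGrid,
    controls: list[VolumeGrid],
    ages: np.ndarray,
    mask: np.ndarray,
) -> TMap:
    """Per-voxel OLS of intensity on [intercept, patient indicator, age].

    ``ages`` lists the patient's age first, then one age per control, in
    the order of ``controls``.  df = (n_controls + 1) - 3.
    """
    if len(controls) < 4:
        raise ValueError("need at least 4 control volumes")
    ages = np.asarray(ages, dtype=float)
    n = len(controls) + 1
    if ages.shape != (n,):
        raise ValueError(f"expected {n} ages (patient first), got {ages.shape}")
    for vol in controls:
        if vol.shape != patient.shape:
            raise ValueError("control volume shape does not match patient volume")
    if mask.shape != patient.shape:
        raise ValueError("mask shape does not match volumes")

    # design: rows = [patient, control_1, ..., control_m]
    X = np.column_stack([np.ones(n), np.r_[1.0, np.zeros(n - 1)], ages])
    Y = np.stack([patient.data[mask]] + [c.data[mask] for c in controls])  # n x V

    df = n - X.shape[1]
    if df < 1:
        raise ValueError("not enough subjects for the 3-regressor model")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # 3 x V
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    var_b1 = sigma2 * XtX_inv[1, 1]

    # zero residual variance up to round-off (scale-relative) -> flagged
    scale = (Y**2).mean(axis=0)
    degenerate_v = var_b1 <= 1e-24 * np.maximum(scale, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_v = beta[1] / np.sqrt(var_b1)
    t_v[degenerate_v] = 0.0
    p_v = 2.0 * stats.t.sf(np.abs(t_v), df)

    t = np.full(mask.shape, np.nan)
    p = np.full(mask.shape, np.nan)
    flag = np.zeros(mask.shape, dtype=bool)
    t[mask], p[mask], flag[mask] = t_v, p_v, degenerate_v
    return TMap(t_values=t, p_values=p, df=df, degenerate=flag)


def extract_clusters(
    tmap: TMap,
    mask: np.ndarray,
    p_threshold: float = 0.01,
    min_extent: int = 100,
    direction: str = "hypo",
    connectivity: int = 18,
) -> ClusterReport:
    """Threshold the t-map and keep connected clusters with strictly more
    than ``min_extent`` voxels, sorted by size descending.

    ``direction``: 'hypo' keeps t < 0 voxels, 'hyper' t > 0, 'two_sided'
    keeps both signs.  Connectivity is 18 by default (6 and 26 available).
    """
    if tmap.t_values.shape != mask.shape:
        raise ValueError("t-map and mask shapes differ")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")

    with np.errstate(invalid="ignore"):
        supra = mask & (tmap.p_values < p_threshold)
        if direction == "hypo":
            supra &= tmap.t_values < 0
        elif direction == "hyper":
            supra &= tmap.t_values > 0
        elif direction != "two_sided":
            raise ValueError(f"unknown direction {direction!r}")

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_labels = ndimage.label(supra, structure=structure)

    clusters: list[Cluster] = []
    for lab in range(1, n_labels + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) <= min_extent:  # strict ">" extent rule
            continue
        tvals = np.abs(tmap.t_values[tuple(coords.T)])
        peak_idx = int(np.argmax(tvals))
        peak = tuple(int(c) for c in coords[peak_idx])
        clusters.append(
            Cluster(
                voxel_count=len(coords),
                peak_t=float(tmap.t_values[peak]),
                peak_coordinate=peak,
                centroid=tuple(float(c) for c in coords.mean(axis=0)),
            )
        )
    clusters.sort(key=lambda c: c.voxel_count, reverse=True)
    return ClusterReport(clusters=clusters, threshold_p=p_threshold, min_extent=min_extent)
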