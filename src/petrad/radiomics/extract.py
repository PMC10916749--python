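"""Whole-volume feature extraction: the 215-entry feature vector."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..grids import VolumeGrid
from .discretize import discretize
from .features import (
    glcm_features,
    gldzm_features,
    glrlm_features,
    glszm_features,
    ngldm_features,
    ngtdm_features,
)
from .firstorder import first_order_features
from .manifest import feature_manifest
from .matrices import (
    _merge,
    glcm_matrices,
    gldzm,
    glrlm_matrices,
    glszm,
    ngldm,
    ngtdm,
)

__all__ = ["ExtractionConfig", "extract_all", "extract_cohort"]


@dataclass
class ExtractionConfig:
    """Feature-extraction parameters.

    n_bins: fixed bin number for gray-level discretization.
    gldm_alpha: gray-level tolerance for the dependence criterion.
    neighborhood_delta: Chebyshev neighborhood radius (1 -> 26 neighbors).
    aggregation: which GLCM/GLRLM matrix the standalone builders return;
        the full vector always contains both merged and averaged variants.
    """

    n_bins: int = 32
    gldm_alpha: int = 0
    neighborhood_delta: int = 1
    glcm_distance: int = 1
    connectivity_zones: int = 26
    aggregation: str = "merged_3d"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.gldm_alpha < 0:
            raise ValueError("gldm_alpha must be >= 0")
        if self.neighborhood_delta < 1:
            raise ValueError("neighborhood_delta must be >= 1")
        if self.aggregation not in ("merged_3d", "per_direction_mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def _directional_features(mats, feature_fn) -> tuple[dict, dict]:
    """(merged-matrix features, per-direction averaged features)."""
    merged = feature_fn(_merge(mats, mats[0].family))
    per_dir = [feature_fn(m) for m in mats if m.Nz > 0]
    if per_dir:
        keys = per_dir[0].keys()
        with np.errstate(invalid="ignore"):
            averaged = {k: float(np.mean([d[k] for d in per_dir])) for k in keys}
    else:
        averaged = {k: float("nan") for k in merged}
    return merged, averaged


def extract_all(
    volume: VolumeGrid, mask: np.ndarray, config: ExtractionConfig | None = None
) -> pd.Series:
    """Compute the manifest-ordered 215-feature vector for one volume.

    Values are floats; features whose definition degenerates on the input
    (for example NGTDM busyness with a single occupied gray level) are NaN
    and left in place rather than dropped.
    """
    config = config or ExtractionConfig()
    if not mask.any():
        raise ValueError("empty mask")
    binned = discretize(volume, mask, config.n_bins)

    feats: dict[str, float] = {}
    feats.update(first_order_features(volume, mask, binned))

    merged, averaged = _directional_features(glcm_matrices(binned), glcm_features)
    feats.update({f"glcm.merged.{k}": v for k, v in merged.items()})
    feats.update({f"glcm.averaged.{k}": v for k, v in averaged.items()})

    merged, averaged = _directional_features(glrlm_matrices(binned), glrlm_features)
    feats.update({f"glrlm.merged.{k}": v for k, v in merged.items()})
    feats.update({f"glrlm.averaged.{k}": v for k, v in averaged.items()})

    feats.update({f"glszm.{k}": v for k, v in glszm_features(glszm(binned)).items()})
    feats.update({f"gldzm.{k}": v for k, v in gldzm_features(gldzm(binned)).items()})
    feats.update({
        f"ngldm.{k}": v
        for k, v in ngldm_features(
            ngldm(binned, alpha=config.gldm_alpha, delta=config.neighborhood_delta)
        ).items()
    })
    feats.update({
        f"ngtdm.{k}": v
        for k, v in ngtdm_features(ngtdm(binned, delta=config.neighborhood_delta)).items()
    })

    manifest = feature_manifest()
    missing = set(manifest) - set(feats)
    if missing:
        raise RuntimeError(f"feature computation incomplete: missing {sorted(missing)[:5]}")
    return pd.Series([feats[name] for name in manifest], index=list(manifest), dtype=float)


def extract_cohort(
    volumes: list[VolumeGrid],
    mask: np.ndarray,
    config: ExtractionConfig | None = None,
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Feature table: one manifest-ordered row per subject."""
    rows = [extract_all(vol, mask, config) for vol in volumes]
    table = pd.DataFrame(rows)
    if subject_ids is not None:
        table.index = pd.Index(subject_ids, name="subject_id")
    return table
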