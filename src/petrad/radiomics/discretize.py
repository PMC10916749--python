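"""Fixed-bin-number intensity discretization.

Gray levels are assigned by dividing the in-mask intensity range into
``n_bins`` equal-width bins:

    level(x) = min( floor((x - min) * n_bins / (max - min)) + 1, n_bins )

so levels run from 1 to ``n_bins`` inside the mask; 0 marks out-of-mask
voxels.  A constant-intensity mask maps everything to level 1.  The rule is
invariant to any positive affine rescaling of the intensities, which makes
every downstream texture feature scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grids import VolumeGrid

__all__ = ["BinnedVolume", "discretize"]


@dataclass
class BinnedVolume:
    """Integer gray-level volume: values 1..n_bins inside the mask, 0 outside."""

    levels: np.ndarray
    n_bins: int
    mask: np.ndarray


def discretize(volume: VolumeGrid, mask: np.ndarray, n_bins: int = 32) -> BinnedVolume:
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume shape")
    if not mask.any():
        raise ValueError("empty mask")
    vals = volume.data[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities inside mask")
    lo, hi = float(vals.min()), float(vals.max())

    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        binned = np.floor((vals - lo) * n_bins / (hi - lo)).astype(np.int32) + 1
        levels[mask] = np.minimum(binned, n_bins)
    return BinnedVolume(levels=levels, n_bins=n_bins, mask=mask)
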