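"""Volumetric containers and NIfTI-1 I/O.

A :class:`VolumeGrid` is the unit every image operation works on: a 3D
intensity array plus voxel geometry.  Brain masks are plain boolean arrays
of the same shape; helper functions here keep the two consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "load_volume", "save_volume", "save_mask", "load_mask"]


def _default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class VolumeGrid:
    """3D intensity volume with voxel geometry.

    Parameters
    ----------
    data:
        3D float array of intensities.
    voxel_size_mm:
        Physical edge lengths of one voxel along each axis, in millimetres.
    affine:
        4x4 voxel-to-world matrix.  Defaults to a diagonal scaling by the
        voxel size (template space, 0-based voxel indices).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def copy_with(self, data: np.ndarray) -> "VolumeGrid":
        """New grid sharing this grid's geometry."""
        return VolumeGrid(data=data, voxel_size_mm=self.voxel_size_mm, affine=self.affine.copy())


def save_volume(vol: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data=np.asanyarray(img.dataobj), voxel_size_mm=zooms, affine=img.affine)


def save_mask(mask: np.ndarray, voxel_size_mm, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _default_affine(tuple(voxel_size_mm)))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(bool)
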