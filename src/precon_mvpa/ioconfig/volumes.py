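"""NIfTI volume and ROI mask handling.

Masks and BOLD series must live on the same voxel lattice; no
resampling is performed. Voxel indices are 0-based; millimetre
coordinates are obtained through the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["RoiMask", "read_volume", "save_volume", "mask_to_array", "VolumeError"]


class VolumeError(ValueError):
    pass


@dataclass
class RoiMask:
    """A named set of voxels on a defined lattice."""

    name: str
    shape: tuple[int, int, int]
    affine: np.ndarray                 # (4, 4)
    indices: np.ndarray                # (n_voxels, 3) int voxel coordinates

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise VolumeError("indices must be (n, 3)")
        if self.indices.shape[0] == 0:
            raise VolumeError(f"mask {self.name!r} is empty")
        if (self.indices < 0).any() or (self.indices >= np.asarray(self.shape)).any():
            raise VolumeError(f"mask {self.name!r} has out-of-lattice voxels")

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float)) - self.affine[:3, 3]
        return np.linalg.solve(self.affine[:3, :3], xyz.T).T

    def extract(self, volume_data: np.ndarray) -> np.ndarray:
        """Pull mask voxels out of a 3-D or 4-D array -> (..., n_voxels)."""
        i, j, k = self.indices.T
        if volume_data.ndim == 3:
            return volume_data[i, j, k]
        if volume_data.ndim == 4:
            return volume_data[i, j, k, :].T      # (volumes, n_voxels)
        raise VolumeError("expected a 3-D or 4-D array")


def read_volume(path: str | Path, expect_4d: bool = False):
    """Read a NIfTI file.

    With ``expect_4d`` the return value is ``(data, affine)`` for a 4-D
    series; otherwise the file is binarized at > 0 and returned as a
    :class:`RoiMask` named after the file stem.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if expect_4d:
        if data.ndim != 4:
            raise VolumeError(f"{path}: expected 4-D data, got {data.ndim}-D")
        return data, np.asarray(img.affine)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected 3-D mask, got {data.ndim}-D")
    indices = np.argwhere(data > 0)
    name = Path(path).name.split(".")[0]
    return RoiMask(name=name, shape=data.shape, affine=np.asarray(img.affine),
                   indices=indices)


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def mask_to_array(mask: RoiMask) -> np.ndarray:
    """Render a mask back to a dense 0/1 volume."""
    vol = np.zeros(mask.shape, dtype=np.uint8)
    i, j, k = mask.indices.T
    vol[i, j, k] = 1
    return vol
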