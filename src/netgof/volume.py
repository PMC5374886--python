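"""Voxel-grid data model and NIfTI I/O.

All computation in this package is purely voxel-grid based: volumes are
assumed to be co-registered, same-shape 3D grids in a common template
space.  Orientation/affine metadata is carried through I/O unmodified but
never used for computation.  Grids are 0-based numpy arrays in the array
index order returned by :func:`nibabel.Nifti1Image.get_fdata` (i, j, k).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "BinaryMask", "read_volume", "write_volume"]


@dataclass
class Volume3D:
    """A 3D scalar volume (SUV, SUVR, Z, mean or SD image, per context).

    Parameters
    ----------
    data : ndarray
        3D float array of voxel values.
    voxel_size_mm : tuple of float
        Edge length of a voxel along each axis, in mm; all > 0.
    affine : ndarray, optional
        4x4 voxel-to-world matrix, carried through I/O only.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D image: got {self.data.ndim} dimensions")
        if min(self.data.shape) < 1:
            raise ValueError("every shape entry must be >= 1")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be three positive reals")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        """New volume with the same grid geometry but different values."""
        return Volume3D(data, self.voxel_size_mm, self.affine)


@dataclass
class BinaryMask:
    """A boolean voxel selection on the same grid as a companion volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D mask: got {self.data.ndim} dimensions")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_shape(self, other) -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: mask {self.shape} vs volume {other.shape}")


def _voxel_sizes(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI volume.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the image is not 3D.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    return Volume3D(data, _voxel_sizes(img), np.asarray(img.affine))


def write_volume(volume: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz), float64 voxel data."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    affine = volume.affine
    if affine is None:
        affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI volume and binarize it (non-zero -> True)."""
    vol = read_volume(path)
    return BinaryMask(vol.data != 0)


def write_mask(mask: BinaryMask, path: str | os.PathLike, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    write_volume(Volume3D(mask.data.astype(np.float64), voxel_size_mm), path)
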