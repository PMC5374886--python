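"""Intensity normalization (SUVR) and Gaussian smoothing.

SUVR divides every voxel by the mean uptake over a reference-region mask
(gray-matter-masked cerebellum in the tau-PET application), so the
returned image has mean exactly 1 over the reference.  Smoothing is a
separable Gaussian at a stated FWHM in mm, converted to a per-axis sigma
in voxels; boundaries are handled by replicating edge values so constant
fields are fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, Volume3D

__all__ = ["SmoothingSpec", "compute_suvr", "gaussian_smooth", "fwhm_to_sigma_voxels"]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing parameters.

    fwhm_mm : full width at half maximum in mm (8 mm in the tau-PET
    application).  boundary_mode is fixed to 'replicate'.
    """

    fwhm_mm: float = 8.0
    boundary_mode: str = "replicate"

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be > 0")
        if self.boundary_mode != "replicate":
            raise ValueError("only 'replicate' boundary handling is supported")


def compute_suvr(suv: Volume3D, reference: BinaryMask) -> Volume3D:
    """Normalize an uptake volume to the scalar mean over a reference mask.

    The reference mean is the unweighted arithmetic mean of the voxels where
    the mask is true; the whole volume is divided by it, so the output has
    mean exactly 1 over the reference and the operation is idempotent.
    """
    reference.check_shape(suv)
    if reference.n_voxels == 0:
        raise ValueError("empty reference region")
    ref_mean = float(suv.data[reference.data].mean())
    if ref_mean <= 0:
        raise ValueError(f"nonpositive reference mean: {ref_mean}")
    return suv.copy_with(suv.data / ref_mean)


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm) -> tuple[float, float, float]:
    """Per-axis Gaussian sigma in voxel units for a FWHM given in mm."""
    return tuple(fwhm_mm / FWHM_PER_SIGMA / v for v in voxel_size_mm)


def gaussian_smooth(volume: Volume3D, spec: SmoothingSpec | float = SmoothingSpec()) -> Volume3D:
    """Separable Gaussian smoothing with replicate boundary handling.

    ``spec`` may be a :class:`SmoothingSpec` or a plain FWHM in mm.
    """
    if not isinstance(spec, SmoothingSpec):
        spec = SmoothingSpec(fwhm_mm=float(spec))
    sigma = fwhm_to_sigma_voxels(spec.fwhm_mm, volume.voxel_size_mm)
    # scipy's 'nearest' mode replicates edge values
    smoothed = ndimage.gaussian_filter(volume.data, sigma=sigma, mode="nearest")
    return volume.copy_with(smoothed)
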