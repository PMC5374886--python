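"""Control-referenced voxelwise Z-score maps.

A control cohort defines a voxelwise reference (mean and sample SD
images); a subject's Z-map expresses each voxel's value in control-SD
units: Z = (subject - control mean) / control SD.  Voxels whose control
SD does not exceed a small floor are marked invalid and excluded from all
downstream statistics rather than clamped, avoiding unbounded Z from
degenerate voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import BinaryMask, Volume3D

__all__ = ["ControlReference", "ZMap", "control_reference", "zscore_map", "mean_zmap"]

DEFAULT_SD_FLOOR = 1e-6


@dataclass
class ControlReference:
    """Voxelwise control mean/SD images plus a validity mask (SD > floor)."""

    mean: Volume3D
    sd: Volume3D
    n_controls: int
    valid: BinaryMask
    sd_floor: float = DEFAULT_SD_FLOOR

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mean.shape


@dataclass
class ZMap:
    """A subject's Z-score volume; values outside ``valid`` are NaN-marked."""

    z: Volume3D
    subject_id: str
    valid: BinaryMask = field(repr=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.z.shape

    def values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid Z values, optionally restricted to an additional boolean mask."""
        sel = self.valid.data if mask is None else (self.valid.data & mask)
        return self.z.data[sel]


def control_reference(
    controls: list[Volume3D], sd_floor: float = DEFAULT_SD_FLOOR
) -> ControlReference:
    """Build the voxelwise control mean and sample SD (denominator n-1).

    At least two control volumes of identical shape are required.  The
    validity mask is true where the SD strictly exceeds ``sd_floor``.
    """
    if len(controls) < 2:
        raise ValueError(f"need >= 2 control volumes, got {len(controls)}")
    if sd_floor < 0:
        raise ValueError("sd_floor must be nonnegative")
    shape = controls[0].shape
    for i, c in enumerate(controls):
        if c.shape != shape:
            raise ValueError(f"shape mismatch: control {i} has {c.shape}, expected {shape}")
    stack = np.stack([c.data for c in controls])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    valid = BinaryMask(sd > sd_floor)
    geom = controls[0]
    return ControlReference(
        mean=geom.copy_with(mean),
        sd=geom.copy_with(sd),
        n_controls=len(controls),
        valid=valid,
        sd_floor=sd_floor,
    )


def zscore_map(subject: Volume3D, ref: ControlReference, subject_id: str = "") -> ZMap:
    """Z = (subject - control mean) / control SD on valid voxels, NaN elsewhere."""
    if subject.shape != ref.shape:
        raise ValueError(f"shape mismatch: subject {subject.shape} vs reference {ref.shape}")
    z = np.full(subject.shape, np.nan)
    sel = ref.valid.data
    z[sel] = (subject.data[sel] - ref.mean.data[sel]) / ref.sd.data[sel]
    return ZMap(z=subject.copy_with(z), subject_id=subject_id, valid=ref.valid)


def mean_zmap(zmaps: list[ZMap]) -> tuple[Volume3D, BinaryMask]:
    """Voxelwise mean Z over subjects, defined where all subjects are valid.

    Returns the mean volume (NaN outside the joint validity mask) and the
    joint mask.  Mismatched validity masks are intersected with a warning.
    """
    if not zmaps:
        raise ValueError("empty list of Z-maps")
    shape = zmaps[0].shape
    joint = np.ones(shape, dtype=bool)
    for zm in zmaps:
        if zm.shape != shape:
            raise ValueError("Z-map shape mismatch")
        joint &= zm.valid.data
    if any(zm.valid.n_voxels != int(joint.sum()) for zm in zmaps):
        import warnings

        warnings.warn("Z-maps have differing validity masks; using their intersection")
    out = np.full(shape, np.nan)
    out[joint] = np.stack([zm.z.data[joint] for zm in zmaps]).mean(axis=0)
    return zmaps[0].z.copy_with(out), BinaryMask(joint)
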