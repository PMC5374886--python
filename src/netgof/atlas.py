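"""Integer-labelled network atlases and label-lookup tables.

An atlas assigns every cortical voxel to exactly one intrinsic
connectivity network (ICN); label 0 marks background / non-cortical
voxels.  Two parcellation levels are supported, following the standard
resting-state parcellation into 7 major networks and 17 subnetworks.
The cortical mask used throughout the package is the atlas's nonzero
support.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import BinaryMask, read_volume

__all__ = [
    "NetworkAtlas",
    "load_atlas",
    "cortical_mask",
    "read_lookup",
    "write_lookup",
    "YEO7_NAMES",
    "YEO17_NAMES",
]

# Canonical 7-network names in the id order used by the tables of the
# underlying parcellation; id order is arbitrary but fixed.
YEO7_NAMES: dict[int, str] = {
    1: "DAN",
    2: "VIS",
    3: "DMN",
    4: "LIM",
    5: "FPN",
    6: "VAN",
    7: "SMN",
}

YEO17_NAMES: dict[int, str] = {
    1: "Higher visual",
    2: "Primary visual",
    3: "Dorsal SMN",
    4: "Ventral SMN-auditory",
    5: "Posterior DAN",
    6: "Frontal eye field DAN",
    7: "Posterior VAN",
    8: "Anterior VAN",
    9: "Temporal pole-anterior MTL LIM",
    10: "Orbitofrontal LIM",
    11: "Precuneus non-DMN",
    12: "FPN component 1",
    13: "FPN component 2",
    14: "Lateral-temporal DMN language",
    15: "Posterior MTL-retrosplenial DMN",
    16: "Midline DMN",
    17: "Anterior DMN",
}

VALID_LEVELS = (7, 17)


@dataclass
class NetworkAtlas:
    """Integer label volume plus id -> name mapping at one parcellation level."""

    labels: np.ndarray
    level: int
    names: dict[int, str]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("non-3D label volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("label volume contains non-integer values")
            self.labels = rounded.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative integers")
        if self.level not in VALID_LEVELS:
            raise ValueError(f"level must be one of {VALID_LEVELS}, got {self.level}")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.names)
        if unknown:
            raise ValueError(f"unknown label id: {sorted(unknown)}")
        empty = set(self.names) - present
        if empty:
            raise ValueError(f"empty network: ids {sorted(empty)} have no voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def network_ids(self) -> list[int]:
        return sorted(self.names)

    def voxel_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=max(self.names) + 1)
        return {k: int(counts[k]) for k in self.network_ids}

    def name_of(self, network_id: int) -> str:
        return self.names[network_id]


def cortical_mask(atlas: NetworkAtlas) -> BinaryMask:
    """Mask of all labelled (cortical) voxels: true exactly where labels > 0."""
    return BinaryMask(atlas.labels > 0)


def read_lookup(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-separated label lookup with columns id, name, level.

    Ids must be unique within each level and 0 (background) must not appear.
    """
    table = pd.read_csv(path, sep="\t", dtype={"id": int, "name": str, "level": int})
    missing = {"id", "name", "level"} - set(table.columns)
    if missing:
        raise ValueError(f"lookup missing columns: {sorted(missing)}")
    if (table["id"] == 0).any():
        raise ValueError("lookup must not contain id 0 (background)")
    for level, sub in table.groupby("level"):
        if sub["id"].duplicated().any():
            dupes = sorted(sub.loc[sub["id"].duplicated(), "id"])
            raise ValueError(f"duplicate ids at level {level}: {dupes}")
    return table


def write_lookup(names_by_level: dict[int, dict[int, str]], path: str | os.PathLike) -> None:
    rows = [
        {"id": i, "name": n, "level": level}
        for level, names in sorted(names_by_level.items())
        for i, n in sorted(names.items())
    ]
    pd.DataFrame(rows, columns=["id", "name", "level"]).to_csv(path, sep="\t", index=False)


def load_atlas(
    label_path: str | os.PathLike,
    lookup_path: str | os.PathLike,
    level: int,
) -> NetworkAtlas:
    """Load an atlas from a NIfTI label volume and a TSV lookup.

    Every nonzero label in the volume must be listed in the lookup at the
    requested level, and every lookup id must have at least one voxel.
    """
    if level not in VALID_LEVELS:
        raise ValueError(f"level must be one of {VALID_LEVELS}, got {level}")
    vol = read_volume(label_path)
    lookup = read_lookup(lookup_path)
    sub = lookup[lookup["level"] == level]
    if sub.empty:
        raise ValueError(f"lookup has no rows for level {level}")
    names = dict(zip(sub["id"].astype(int), sub["name"]))
    return NetworkAtlas(vol.data, level, names, vol.voxel_size_mm, vol.affine)
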