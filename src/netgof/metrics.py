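"""Per-network mean-Z and goodness-of-fit (GOF) scores.

For a subject Z-map and a labelled network atlas, the mean Z within a
network template measures the extent of pathology in that network, and
the GOF score measures spatial preference: mean Z inside the template
minus the mean Z of cortical voxels outside it.  "Cortical voxels
outside" means valid voxels carrying a different nonzero atlas label;
background voxels never dilute the outside mean.  A spatially uniform
Z-map therefore has GOF 0 for every network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas
from .zmap import ZMap

__all__ = ["network_mean_z", "gof_score", "score_cohort", "rank_networks", "SCORE_COLUMNS"]

SCORE_COLUMNS = [
    "subject_id",
    "level",
    "network_id",
    "network_name",
    "mean_z",
    "gof",
    "n_voxels_in",
    "n_voxels_out",
]


def _check_network(atlas: NetworkAtlas, network_id: int) -> None:
    if network_id not in atlas.names:
        raise ValueError(f"unknown network id {network_id} at level {atlas.level}")


def network_mean_z(zmap: ZMap, atlas: NetworkAtlas, network_id: int) -> float:
    """Unweighted mean of Z over valid voxels labelled ``network_id``."""
    _check_network(atlas, network_id)
    if zmap.shape != atlas.shape:
        raise ValueError("Z-map and atlas shapes differ")
    sel = (atlas.labels == network_id) & zmap.valid.data
    if not sel.any():
        raise ValueError(f"no valid voxels in network {network_id}")
    return float(zmap.z.data[sel].mean())


def gof_score(zmap: ZMap, atlas: NetworkAtlas, network_id: int) -> float:
    """Mean Z inside the network minus mean Z of other-network cortical voxels."""
    _check_network(atlas, network_id)
    if zmap.shape != atlas.shape:
        raise ValueError("Z-map and atlas shapes differ")
    inside = (atlas.labels == network_id) & zmap.valid.data
    outside = (atlas.labels > 0) & (atlas.labels != network_id) & zmap.valid.data
    if not inside.any():
        raise ValueError(f"no valid voxels in network {network_id}")
    if not outside.any():
        raise ValueError(f"network {network_id} covers the entire valid cortex")
    return float(zmap.z.data[inside].mean() - zmap.z.data[outside].mean())


def score_cohort(zmaps: list[ZMap], atlas: NetworkAtlas) -> pd.DataFrame:
    """Per-subject, per-network score table (K rows per subject).

    Columns: subject_id, level, network_id, network_name, mean_z, gof,
    n_voxels_in, n_voxels_out.
    """
    if not zmaps:
        raise ValueError("empty cohort")
    rows = []
    for zm in zmaps:
        if zm.shape != atlas.shape:
            raise ValueError(f"subject {zm.subject_id!r}: Z-map and atlas shapes differ")
        valid = zm.valid.data
        cortex_valid = (atlas.labels > 0) & valid
        n_cortex = int(cortex_valid.sum())
        z = zm.z.data
        for k in atlas.network_ids:
            inside = (atlas.labels == k) & valid
            n_in = int(inside.sum())
            n_out = n_cortex - n_in
            if n_in == 0:
                raise ValueError(f"subject {zm.subject_id!r}: no valid voxels in network {k}")
            if n_out == 0:
                raise ValueError(
                    f"subject {zm.subject_id!r}: network {k} covers the entire valid cortex"
                )
            mean_in = float(z[inside].mean())
            mean_out = float(z[cortex_valid & ~inside].mean())
            rows.append(
                {
                    "subject_id": zm.subject_id,
                    "level": atlas.level,
                    "network_id": k,
                    "network_name": atlas.name_of(k),
                    "mean_z": mean_in,
                    "gof": mean_in - mean_out,
                    "n_voxels_in": n_in,
                    "n_voxels_out": n_out,
                }
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def rank_networks(summary: pd.DataFrame) -> list[int]:
    """Network ids sorted by descending group-mean mean_z; ties by ascending id.

    ``summary`` needs columns ``network_id`` and ``mean`` restricted to the
    mean_z metric (as produced by :func:`netgof.inference.summarize_group`),
    or a raw score table with ``mean_z``, which is then averaged by network.
    """
    if "mean" in summary.columns:
        sub = summary
        if "metric" in sub.columns:
            sub = sub[sub["metric"] == "mean_z"]
        means = sub.set_index("network_id")["mean"]
    elif "mean_z" in summary.columns:
        means = summary.groupby("network_id")["mean_z"].mean().rename("mean")
    else:
        raise ValueError("summary must carry a 'mean' or 'mean_z' column")
    order = means.reset_index().sort_values(
        ["mean", "network_id"], ascending=[False, True], kind="mergesort"
    )
    return [int(i) for i in order["network_id"]]
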