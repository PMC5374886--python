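"""Model/Results interface over the network-correspondence analysis.

`NetworkCorrespondenceModel` bundles a patient cohort's Z-score maps (or a
precomputed score table) with a network atlas; `fit()` runs the per-network
scoring and group inference and returns a `NetworkCorrespondenceResults`
carrying the estimates (group mean mean-Z and GOF per network), their
uncertainties (SDs, t statistics, two-tailed p), the Bonferroni-corrected
decisions, and the network ranking, with a printable `summary()` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas
from .inference import bonferroni_alpha, format_alpha, summarize_group
from .metrics import rank_networks, score_cohort
from .zmap import ZMap

__all__ = ["NetworkCorrespondenceModel", "NetworkCorrespondenceResults"]


class NetworkCorrespondenceModel:
    """Spatial correspondence of a cohort's Z-score maps with network templates.

    Parameters
    ----------
    zmaps : list of ZMap or None
        Patient Z-score maps (control-referenced).  May be omitted when a
        precomputed score table is supplied via :meth:`from_scores`.
    atlas : NetworkAtlas
        Labelled parcellation at level 7 or 17; its nonzero support defines
        the cortical mask.

    Examples
    --------
    >>> model = NetworkCorrespondenceModel(zmaps, atlas)   # doctest: +SKIP
    >>> res = model.fit(alpha_fw=0.05)                     # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(self, zmaps: list[ZMap] | None, atlas: NetworkAtlas):
        self.zmaps = zmaps
        self.atlas = atlas
        self._scores: pd.DataFrame | None = None

    @classmethod
    def from_scores(cls, scores: pd.DataFrame, atlas: NetworkAtlas) -> "NetworkCorrespondenceModel":
        """Build the model from a per-subject, per-network score table."""
        model = cls(None, atlas)
        model._scores = scores
        return model

    @property
    def scores(self) -> pd.DataFrame:
        """Per-subject, per-network mean-Z / GOF table (computed lazily)."""
        if self._scores is None:
            if not self.zmaps:
                raise ValueError("model holds neither Z-maps nor a score table")
            self._scores = score_cohort(self.zmaps, self.atlas)
        return self._scores

    def fit(self, alpha_fw: float = 0.05) -> "NetworkCorrespondenceResults":
        """Run group inference at familywise level ``alpha_fw``."""
        scores = self.scores
        summary = summarize_group(scores, alpha_fw=alpha_fw)
        return NetworkCorrespondenceResults(self, scores, summary, alpha_fw)


class NetworkCorrespondenceResults:
    """Fitted per-network estimates, tests and ranking.

    Attributes
    ----------
    scores : DataFrame
        The per-subject score table the fit was computed from.
    summary_frame : DataFrame
        Per network x metric: mean, sd, n, t, df, p_two_tailed,
        alpha_corrected, significant; sorted by descending mean per metric.
    """

    def __init__(self, model, scores, summary_frame, alpha_fw):
        self.model = model
        self.scores = scores
        self.summary_frame = summary_frame
        self.alpha_fw = alpha_fw

    @property
    def level(self) -> int:
        return self.model.atlas.level

    @property
    def n_subjects(self) -> int:
        return int(self.scores["subject_id"].nunique())

    @property
    def alpha_corrected(self) -> float:
        return bonferroni_alpha(self.alpha_fw, len(self.model.atlas.names))

    @property
    def ranking(self) -> list[int]:
        """Network ids by descending group-mean mean-Z (ties by ascending id)."""
        return rank_networks(self.summary_frame)

    @property
    def ranking_names(self) -> list[str]:
        return [self.model.atlas.name_of(k) for k in self.ranking]

    def significant_networks(self, metric: str = "mean_z") -> list[int]:
        sub = self.summary_frame
        sel = sub[(sub["metric"] == metric) & sub["significant"]]
        return [int(k) for k in sel["network_id"]]

    def summary(self) -> str:
        """Human-readable table (3-decimal formatting, as in the field's tables)."""
        lines = [
            f"Network correspondence, {self.level}-network level, "
            f"n = {self.n_subjects} subjects",
            f"One-sample t-test, test value = 0; "
            f"Bonferroni-corrected alpha = {format_alpha(self.alpha_corrected)}",
            "",
            f"{'metric':8s} {'network':32s} {'Mean':>8s} {'SD':>8s} {'t':>8s} "
            f"{'p(2-tail)':>10s} {'sig':>4s}",
        ]
        for _, row in self.summary_frame.iterrows():
            lines.append(
                f"{row['metric']:8s} {row['network_name'][:32]:32s} "
                f"{row['mean']:8.3f} {row['sd']:8.3f} {row['t']:8.3f} "
                f"{row['p_two_tailed']:10.3f} {'*' if row['significant'] else '':>4s}"
            )
        lines.append("")
        lines.append("Ranking by mean Z: " + " > ".join(self.ranking_names))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<NetworkCorrespondenceResults level={self.level} "
            f"n={self.n_subjects} alpha_fw={self.alpha_fw}>"
        )
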