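"""Group-level inference on network scores and cross-cohort correlation.

One-sample t-tests (test value 0) assess, per network, whether the
patient group's mean-Z differs from the control baseline and whether the
GOF score is positive.  Significance is Bonferroni-corrected for the
number of networks at the parcellation level; decisions use the
unrounded threshold, display uses 3 decimals.  Cross-cohort spatial
agreement is the Pearson correlation of two mean Z-maps over a cortical
mask; its p-value assumes voxel independence and is reported only as a
flagged, anti-conservative reference — the headline quantity is r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import BinaryMask, Volume3D

__all__ = [
    "TestResult",
    "CrossCohortResult",
    "one_sample_t",
    "summary_t",
    "bonferroni_alpha",
    "format_alpha",
    "summarize_group",
    "voxelwise_correlation",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "metric",
    "network_id",
    "network_name",
    "mean",
    "sd",
    "n",
    "t",
    "df",
    "p_two_tailed",
    "alpha_corrected",
    "significant",
]


@dataclass(frozen=True)
class TestResult:
    """One-sample t-test result: statistic, degrees of freedom, two-tailed p."""

    t: float
    df: int
    p_two_tailed: float


@dataclass(frozen=True)
class CrossCohortResult:
    """Pearson correlation of two statistic maps over a shared voxel mask.

    ``p`` assumes independent voxels; spatially smooth maps violate this,
    so ``p`` is anti-conservative and ``r`` is the quantity to report.
    """

    r: float
    n_voxels: int
    p: float


def _two_tailed_p(t: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """t = (mean - mu0) / (s / sqrt(n)) with sample SD (n-1), exact t CDF p."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need n >= 2 values, got {n}")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero SD: t statistic undefined")
    t = (float(x.mean()) - mu0) / (sd / math.sqrt(n))
    return TestResult(t=t, df=n - 1, p_two_tailed=_two_tailed_p(t, n - 1))


def summary_t(mean: float, sd: float, n: int) -> TestResult:
    """One-sample t against 0 recomputed from summary statistics."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    t = mean / (sd / math.sqrt(n))
    return TestResult(t=t, df=n - 1, p_two_tailed=_two_tailed_p(t, n - 1))


def bonferroni_alpha(alpha_fw: float, k: int) -> float:
    """Per-test threshold alpha_fw / k (unrounded; use format_alpha to display)."""
    if not 0 < alpha_fw <= 1:
        raise ValueError("alpha_fw must be in (0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha_fw / k


def format_alpha(alpha: float) -> str:
    """Display form of a threshold, rounded to 3 decimals (0.05/7 -> '0.007')."""
    return f"{alpha:.3f}"


def summarize_group(scores: pd.DataFrame, alpha_fw: float = 0.05) -> pd.DataFrame:
    """Per network x metric group summary mirroring the published table layout.

    For each network and each of the two metrics (mean_z, gof): group mean,
    sample SD, one-sample t against 0, df, two-tailed p, the Bonferroni
    threshold alpha_fw/K (K = number of networks in the table), and the
    significance flag p < threshold.  Rows are sorted by descending mean
    within metric.
    """
    n_subjects = scores["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects for group inference")
    networks = scores[["network_id", "network_name"]].drop_duplicates()
    alpha_c = bonferroni_alpha(alpha_fw, len(networks))
    rows = []
    for metric in ("mean_z", "gof"):
        for _, net in networks.iterrows():
            vals = scores.loc[scores["network_id"] == net["network_id"], metric].to_numpy()
            res = one_sample_t(vals)
            rows.append(
                {
                    "metric": metric,
                    "network_id": int(net["network_id"]),
                    "network_name": net["network_name"],
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "n": int(vals.size),
                    "t": res.t,
                    "df": res.df,
                    "p_two_tailed": res.p_two_tailed,
                    "alpha_corrected": alpha_c,
                    "significant": bool(res.p_two_tailed < alpha_c),
                }
            )
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    out = (
        out.sort_values(["metric", "mean"], ascending=[True, False], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def voxelwise_correlation(
    map_a: Volume3D, map_b: Volume3D, mask: BinaryMask
) -> CrossCohortResult:
    """Pearson r between two maps over the masked voxels.

    The two-tailed p uses the t transform with df = n_voxels - 2 and is
    flagged as assuming voxel independence (see :class:`CrossCohortResult`).
    """
    mask.check_shape(map_a)
    mask.check_shape(map_b)
    if map_a.shape != map_b.shape:
        raise ValueError("map shapes differ")
    a = map_a.data[mask.data]
    b = map_b.data[mask.data]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 3:
        raise ValueError(f"mask too small: {n} usable voxels, need >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate variance within mask")
    am, bm = a - a.mean(), b - b.mean()
    r = float(am @ bm / np.sqrt((am @ am) * (bm @ bm)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = _two_tailed_p(t, n - 2)
    return CrossCohortResult(r=r, n_voxels=n, p=p)
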