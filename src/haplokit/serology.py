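"""Autoantigen-array analysis.

Control-channel normalization of net fluorescence intensities, genotype-
group enrichment with fold flagging, and an average-linkage antigen
clustering order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "EnrichmentResult",
    "CONTROL_ROW",
    "normalize_nfi",
    "group_enrichment",
    "antigen_cluster_order",
]

CONTROL_ROW = "__control__"
LOG_FLOOR = 1.0
FOLD_FLOOR = 0.1


@dataclass
class EnrichmentResult:
    antigen: str
    fold: float
    p: float
    flagged: bool


def normalize_nfi(S: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's antigen values by its control-channel intensity.

    The reserved ``__control__`` row supplies the per-array channel; the
    result is rescaled so the cohort-median control maps to 1 (i.e. values
    keep the scale of a typical array).  Samples with a zero control channel
    are dropped with a warning.
    """
    if CONTROL_ROW not in S.index:
        raise ValueError(f"matrix lacks the reserved {CONTROL_ROW!r} row")
    control = S.loc[CONTROL_ROW]
    good = control > 0
    if not good.all():
        warnings.warn(
            f"{int((~good).sum())} samples with zero control channel excluded"
        )
    S = S.loc[:, good]
    control = control[good]
    median_c = float(control.median())
    out = S.drop(index=CONTROL_ROW).div(control / median_c, axis=1)
    return out / median_c


def group_enrichment(
    S: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "risk",
    group_b: str = "protective",
    fold_threshold: float = 5.0,
    use_median: bool = False,
) -> tuple[list[EnrichmentResult], dict]:
    """Per-antigen fold enrichment of group_a over group_b plus the
    per-sample mean-NFI comparison.

    Folds are ratios of group means (or medians) with a pseudo-floor;
    p-values are Welch t on log-scale values; antigens are flagged when
    fold > fold_threshold.
    """
    groups = groups.loc[[s for s in S.columns if s in groups.index]]
    a_samples = groups.index[groups == group_a]
    b_samples = groups.index[groups == group_b]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("need >= 2 samples per compared group")
    A = S[a_samples].to_numpy(dtype=float)
    B = S[b_samples].to_numpy(dtype=float)

    center = np.median if use_median else np.mean
    results = []
    for i, antigen in enumerate(S.index):
        ma = max(float(center(A[i])), FOLD_FLOOR)
        mb = max(float(center(B[i])), FOLD_FLOOR)
        fold = ma / mb
        p = float(
            stats.ttest_ind(
                np.log(A[i] + LOG_FLOOR), np.log(B[i] + LOG_FLOOR), equal_var=False
            ).pvalue
        )
        results.append(
            EnrichmentResult(antigen=antigen, fold=fold, p=p, flagged=fold > fold_threshold)
        )

    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    sample_cmp = {
        "mean_a": float(mean_a.mean()),
        "mean_b": float(mean_b.mean()),
        "p": float(
            stats.ttest_ind(
                np.log(mean_a + LOG_FLOOR), np.log(mean_b + LOG_FLOOR), equal_var=False
            ).pvalue
        ),
    }
    return results, sample_cmp


def antigen_cluster_order(S: pd.DataFrame) -> list[str]:
    """Average-linkage clustering order on correlation distance."""
    if S.shape[0] < 3:
        return list(S.index)
    corr = np.corrcoef(S.to_numpy(dtype=float))
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    return [S.index[i] for i in leaves]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "antigen": [r.antigen for r in results],
            "fold": [r.fold for r in results],
            "p": [r.p for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
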