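"""cis-eQTL dosage regression and diplotype-ordered expression trends."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EqtlResult",
    "normalize_expression",
    "cis_eqtl",
    "diplotype_trend",
]


@dataclass
class EqtlResult:
    gene: str
    variant: str
    beta: float
    t_stat: float
    p: float
    n: int
    group_medians: dict
    testable: bool = True


def _inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (offset 0.5 / n)."""
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(values))


def normalize_expression(
    M: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene inverse-normal transform, then OLS residualization against
    covariates (categorical columns are dummy-coded).

    Returns the normalized genes x samples matrix and the list of genes that
    were constant (set to all zeros).
    """
    if M.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    out = np.zeros(M.shape)
    flagged = []
    for i, gene in enumerate(M.index):
        row = M.iloc[i].to_numpy(dtype=float)
        if np.allclose(row, row[0]):
            flagged.append(gene)
            continue
        out[i] = _inverse_normal(row)
    if covariates is not None:
        cov = covariates.loc[list(M.columns)]
        X = pd.get_dummies(cov, drop_first=True).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(cov)), X])
        # residualize every gene against the covariate design
        beta, *_ = np.linalg.lstsq(X, out.T, rcond=None)
        out = (out.T - X @ beta).T
    return pd.DataFrame(out, index=M.index, columns=M.columns), flagged


def cis_eqtl(values, dose, gene: str = "", variant: str = "") -> EqtlResult:
    """Simple linear regression of expression on allele dose (0/1/2).

    Negative beta means the alternate allele lowers expression.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(dose, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    medians = {
        int(g): float(np.median(y[x == g])) for g in sorted(np.unique(x))
    }
    if len(np.unique(x)) < 2:
        return EqtlResult(gene, variant, float("nan"), float("nan"), float("nan"),
                          len(y), medians, testable=False)
    reg = stats.linregress(x, y)
    t = reg.slope / reg.stderr if reg.stderr > 0 else float("inf") * np.sign(reg.slope)
    return EqtlResult(
        gene=gene,
        variant=variant,
        beta=float(reg.slope),
        t_stat=float(t),
        p=float(reg.pvalue),
        n=int(len(y)),
        group_medians=medians,
    )


def diplotype_trend(values, scores, gene: str = "") -> EqtlResult:
    """Regression of expression on the 0..4 diplotype score with per-class
    medians (dose-effect trend)."""
    return cis_eqtl(values, scores, gene=gene, variant="diplotype_score")
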