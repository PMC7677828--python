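"""Internal-standards differential expression.

A reference group of low-variability, above-background genes is selected by
an iterative F screen on control samples.  Samples are normalized by a
two-step procedure (median scaling to a fixed target, then per-sample affine
detrending against the stored reference profile, iterated to a fixed point).
Genes are called by a replicate Student t test plus an associative T test of
the gene's replicated residuals against the pooled reference residuals, with
expression-floor and fold-change filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceModel",
    "DeConfig",
    "DeResult",
    "build_reference_group",
    "two_step_normalize",
    "associative_t_test",
    "run_de",
]

MIN_REFERENCE_GENES = 20
FOLD_PSEUDO_FLOOR = 0.1


@dataclass
class DeConfig:
    background_rpkm: float = 2.0
    t_alpha: float = 0.05
    assoc_alpha: float = 1e-4
    min_fold: float = 1.5
    f_alpha: float = 0.05
    welch: bool = False

    def __post_init__(self) -> None:
        for name in ("t_alpha", "assoc_alpha", "f_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_fold <= 0:
            raise ValueError("min_fold must be > 0")


@dataclass
class ReferenceModel:
    reference_genes: list[str]
    residual_pool: np.ndarray
    tech_variance: float
    median_target: float
    mean_profile: pd.Series  # across-sample mean over reference genes
    n_control_samples: int = 0

    def __post_init__(self) -> None:
        if self.tech_variance <= 0:
            raise ValueError("tech_variance must be > 0")


@dataclass
class DeResult:
    gene: str
    fold: float
    p_t: float
    p_assoc: float
    mean_case: float
    mean_ctrl: float
    passed: bool
    failing: str = ""


def _median_scale(M: pd.DataFrame, genes: list[str], target: float) -> pd.DataFrame:
    medians = M.loc[genes].median(axis=0)
    if (medians <= 0).any():
        bad = medians.index[medians <= 0].tolist()
        raise ValueError(f"non-positive reference medians for samples {bad}")
    return M.mul(target / medians, axis=1)


def build_reference_group(M_ctrl: pd.DataFrame, cfg: DeConfig | None = None) -> ReferenceModel:
    """Iterative selection of an equal-expression internal standard.

    Candidates are genes with mean expression above the background floor.
    After per-sample median scaling, genes whose variance ratio against the
    pooled candidate variance rejects the F test (high side) are dropped;
    the screen repeats until stable.  The residual pool collects each
    surviving gene's deviations from its mean, scaled by the pooled SD.
    """
    cfg = cfg or DeConfig()
    if M_ctrl.shape[1] < 3:
        raise ValueError("need >= 3 control samples")
    n = M_ctrl.shape[1]
    candidates = [g for g in M_ctrl.index if M_ctrl.loc[g].mean() > cfg.background_rpkm]
    if len(candidates) < MIN_REFERENCE_GENES:
        raise ValueError(
            f"only {len(candidates)} genes above background; reference pool too small"
        )
    target = float(np.median(M_ctrl.loc[candidates].median(axis=0)))
    current = sorted(candidates)
    for _ in range(100):
        scaled = _median_scale(M_ctrl, current, target).loc[current]
        variances = scaled.var(axis=1, ddof=1)
        pooled = float(variances.mean())
        dfn = n - 1
        dfd = (len(current) - 1) * (n - 1)
        crit = stats.f.isf(cfg.f_alpha, dfn, dfd)
        keep = sorted(variances.index[variances / pooled <= crit])
        if keep == current:
            break
        if len(keep) < MIN_REFERENCE_GENES:
            raise ValueError(
                f"reference group shrank to {len(keep)} genes; pool too small"
            )
        current = keep

    scaled = _median_scale(M_ctrl, current, target).loc[current]
    tech_variance = float(scaled.var(axis=1, ddof=1).mean())
    resid = scaled.sub(scaled.mean(axis=1), axis=0) / np.sqrt(tech_variance)
    return ReferenceModel(
        reference_genes=current,
        residual_pool=resid.to_numpy().ravel(),
        tech_variance=tech_variance,
        median_target=target,
        mean_profile=scaled.mean(axis=1),
        n_control_samples=n,
    )


def two_step_normalize(
    M: pd.DataFrame, ref: ReferenceModel, tol: float = 1e-12, max_iter: int = 100
) -> pd.DataFrame:
    """Two-step normalization against the stored reference model.

    Step 1 scales each sample so its median over the reference genes equals
    the model's fixed target; step 2 fits each sample's reference-gene
    values on the stored mean reference profile and removes the affine
    trend.  The two steps are iterated to a fixed point, making the whole
    transform idempotent.
    """
    genes = [g for g in ref.reference_genes if g in M.index]
    if len(genes) < len(ref.reference_genes):
        warnings.warn(
            f"{len(ref.reference_genes) - len(genes)} reference genes missing; "
            "proceeding with the intersection"
        )
    if not genes:
        raise ValueError("no reference genes present in matrix")
    profile = ref.mean_profile.loc[genes].to_numpy()
    X = np.column_stack([np.ones(len(genes)), profile])
    # a flat reference profile carries no trend signal: detrending against
    # it would fit noise, so step 2 is skipped unless the profile's spread
    # exceeds its own sampling noise
    noise_floor = 10.0 * ref.tech_variance / max(ref.n_control_samples, 1)
    detrend = float(np.var(profile, ddof=1)) > noise_floor

    out = M.astype(float).copy()
    for _ in range(max_iter):
        # step 1: per-sample median scaling to the fixed target
        medians = out.loc[genes].median(axis=0)
        if (medians <= 0).any():
            raise ValueError("non-positive reference median during normalization")
        scale = ref.median_target / medians
        out = out.mul(scale, axis=1)
        if not detrend:
            if np.abs(scale - 1).max() < tol:
                break
            continue
        # step 2: per-sample affine detrend against the stored profile
        Y = out.loc[genes].to_numpy()
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (2, n_samples)
        a, b = coef[0], coef[1]
        if (b <= 0).any():
            raise ValueError("non-positive detrending slope")
        out = out.sub(a, axis=1).div(b, axis=1)
        if np.abs(scale - 1).max() < tol and np.abs(a).max() < tol and np.abs(b - 1).max() < tol:
            break
    return out


def associative_t_test(residuals, pool, welch: bool = False) -> float:
    """Two-sided p comparing a gene's replicated residuals with the pooled
    reference residual distribution (Student t by default)."""
    r = np.asarray(residuals, dtype=float)
    p = np.asarray(pool, dtype=float)
    if len(r) < 2:
        raise ValueError("need >= 2 experimental replicates")
    if len(p) < 100:
        raise ValueError("reference residual pool too small (< 100)")
    if r.std(ddof=1) == 0 and p.std(ddof=1) == 0:
        return 1.0 if np.isclose(r.mean(), p.mean()) else 0.0
    res = stats.ttest_ind(r, p, equal_var=not welch)
    return float(res.pvalue)


def _student_t_rows(X: np.ndarray, Y: np.ndarray, welch: bool = False) -> np.ndarray:
    """Row-wise two-sided two-sample t p-values; Y may be a single row
    shared by every row of X (the reference pool)."""
    n1, n2 = X.shape[1], Y.shape[1]
    m1, m2 = X.mean(axis=1), Y.mean(axis=1)
    v1 = X.var(axis=1, ddof=1)
    v2 = Y.var(axis=1, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / (
            np.where(v1 > 0, (v1 / n1) ** 2 / (n1 - 1), 0)
            + np.where(v2 > 0, (v2 / n2) ** 2 / (n2 - 1), 0)
            + 1e-300
        )
    else:
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = s2 * (1 / n1 + 1 / n2)
        df = np.full(X.shape[0], n1 + n2 - 2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = se2 <= 0
    if np.any(degenerate):
        p = np.where(degenerate & np.isclose(m1, m2), 1.0, np.where(degenerate, 0.0, p))
    return p


def run_de(
    M_case: pd.DataFrame, M_ctrl: pd.DataFrame, cfg: DeConfig | None = None
) -> tuple[list[DeResult], ReferenceModel]:
    """Full internal-standards DE pipeline.

    Reference group from control data -> two-step normalization of both
    groups -> per-gene Student t (case vs control, normalized scale) ->
    associative T test of the case residuals against the reference pool ->
    background and fold filters.
    """
    cfg = cfg or DeConfig()
    if M_case.shape[1] < 2 or M_ctrl.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    genes = [g for g in M_case.index if g in set(M_ctrl.index)]
    M_case = M_case.loc[genes]
    M_ctrl = M_ctrl.loc[genes]

    ref = build_reference_group(M_ctrl, cfg)
    norm_case = two_step_normalize(M_case, ref)
    norm_ctrl = two_step_normalize(M_ctrl, ref)
    sd = np.sqrt(ref.tech_variance)

    case_raw = M_case.to_numpy(dtype=float)
    ctrl_raw = M_ctrl.to_numpy(dtype=float)
    case_n = norm_case.to_numpy(dtype=float)
    ctrl_n = norm_ctrl.to_numpy(dtype=float)

    mean_case = case_raw.mean(axis=1)
    mean_ctrl = ctrl_raw.mean(axis=1)
    fold_raw = np.maximum(mean_case, FOLD_PSEUDO_FLOOR) / np.maximum(
        mean_ctrl, FOLD_PSEUDO_FLOOR
    )
    fold = np.maximum(fold_raw, 1.0 / fold_raw)

    p_t = _student_t_rows(case_n, ctrl_n, welch=cfg.welch)
    residuals = (case_n - ctrl_n.mean(axis=1, keepdims=True)) / sd
    pool = ref.residual_pool[None, :]
    p_assoc = _student_t_rows(residuals, pool, welch=cfg.welch)

    results: list[DeResult] = []
    for i, gene in enumerate(genes):
        failing = []
        if not p_t[i] < cfg.t_alpha:
            failing.append("p_t")
        if not p_assoc[i] < cfg.assoc_alpha:
            failing.append("p_assoc")
        if not fold[i] > cfg.min_fold:
            failing.append("fold")
        if not max(mean_case[i], mean_ctrl[i]) > cfg.background_rpkm:
            failing.append("background")
        results.append(
            DeResult(
                gene=gene,
                fold=float(fold[i]),
                p_t=float(p_t[i]),
                p_assoc=float(p_assoc[i]),
                mean_case=float(mean_case[i]),
                mean_ctrl=float(mean_ctrl[i]),
                passed=not failing,
                failing=",".join(failing),
            )
        )
    return results, ref


def de_frame(results: list[DeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "fold": [r.fold for r in results],
            "p_t": [r.p_t for r in results],
            "p_assoc": [r.p_assoc for r in results],
            "mean_case": [r.mean_case for r in results],
            "mean_ctrl": [r.mean_ctrl for r in results],
            "passed": [r.passed for r in results],
            "failing": [r.failing for r in results],
        }
    )
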