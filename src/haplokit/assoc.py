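"""Single-variant association machinery.

Allelic 2x2 tests with Woolf confidence intervals, median-based genomic
control, Benjamini-Hochberg FDR, Cochran-Mantel-Haenszel stratified tests
and conditional scans on a peak variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "AssocResult",
    "InflationEstimate",
    "CmhResult",
    "allelic_test",
    "genomic_control",
    "apply_genomic_control",
    "bh_fdr",
    "cmh_test",
    "conditional_scan",
]

# median of the 1-df chi-square distribution
CHI2_1_MEDIAN = float(stats.chi2.median(df=1))  # 0.454936...


@dataclass
class AssocResult:
    variant_id: str
    table: tuple[int, int, int, int]  # case_alt, case_ref, ctrl_alt, ctrl_ref
    or_: float
    ci95: tuple[float, float]
    chi2: float
    p_raw: float
    p_gc: float = float("nan")
    p_fdr: float = float("nan")
    testable: bool = True


@dataclass
class InflationEstimate:
    lambda_: float
    n_tests: int

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be > 0")


@dataclass
class CmhResult:
    id: str
    strata_tables: list[tuple[int, int, int, int]]
    or_mh: float
    chi2_cmh: float
    p: float
    testable: bool = True


def allelic_test(
    case_alt: int, case_ref: int, ctrl_alt: int, ctrl_ref: int, variant_id: str = ""
) -> AssocResult:
    """Basic allelic 2x2 test.

    chi2 is the Pearson statistic n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the
    odds ratio uses a Haldane-Anscombe +0.5 on every cell when any cell is
    zero; the 95% CI is Woolf's interval on log OR.
    """
    a, b, c, d = case_alt, case_ref, ctrl_alt, ctrl_ref
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    testable = all(x > 0 for x in (a + b, c + d, a + c, b + d))
    if testable:
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = float("nan"), float("nan")
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = float(a), float(b), float(c), float(d)
    or_ = (a2 * d2) / (b2 * c2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return AssocResult(
        variant_id=variant_id,
        table=(a, b, c, d),
        or_=float(or_),
        ci95=(float(lo), float(hi)),
        chi2=float(chi2),
        p_raw=p,
        testable=testable,
    )


def genomic_control(chi2_values) -> InflationEstimate:
    """Median-based genomic inflation factor: median(chi2) / median(chi2_1)."""
    vals = np.asarray([v for v in chi2_values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no finite chi-square statistics")
    return InflationEstimate(
        lambda_=float(np.median(vals) / CHI2_1_MEDIAN), n_tests=int(vals.size)
    )


def apply_genomic_control(chi2: float, lambda_: float) -> float:
    """Inflation-corrected p-value; statistics are only ever deflated."""
    corrected = chi2 / lambda_ if lambda_ > 1.0 else chi2
    return float(stats.chi2.sf(corrected, df=1))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def cmh_test(
    strata_tables, id: str = "", continuity_correction: bool = False
) -> CmhResult:
    """Cochran-Mantel-Haenszel common odds ratio and 1-df test.

    Each table is (a, b, c, d) = (case_alt, case_ref, ctrl_alt, ctrl_ref).
    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the chi-square uses the
    hypergeometric mean and variance of a_i, by default without continuity
    correction.
    """
    tables = [tuple(int(x) for x in t) for t in strata_tables]
    if not tables:
        raise ValueError("at least one stratum required")
    num = den = 0.0
    dev = var = 0.0
    any_testable = False
    for a, b, c, d in tables:
        n = a + b + c + d
        if n == 0:
            raise ValueError("empty stratum table")
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        num += a * d / n
        den += b * c / n
        if min(r1, r2, c1, c2) > 0:
            any_testable = True
            dev += a - r1 * c1 / n
            if n > 1:
                var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if not any_testable or var == 0:
        if num == 0 and den == 0:
            return CmhResult(id, tables, float("nan"), float("nan"), float("nan"), False)
        or_mh = num / den if den > 0 else float("inf")
        return CmhResult(id, tables, or_mh, float("nan"), float("nan"), False)
    if den == 0 or num == 0:
        # zero-cell strata everywhere: fall back to 0.5-corrected sums
        num = sum((a + 0.5) * (d + 0.5) / (a + b + c + d + 2) for a, b, c, d in tables)
        den = sum((b + 0.5) * (c + 0.5) / (a + b + c + d + 2) for a, b, c, d in tables)
    or_mh = num / den
    adj = abs(dev) - 0.5 if continuity_correction else abs(dev)
    adj = max(adj, 0.0)
    chi2 = adj * adj / var
    return CmhResult(id, tables, float(or_mh), float(chi2), float(stats.chi2.sf(chi2, df=1)))


def _allele_table(col: np.ndarray, is_case: np.ndarray) -> tuple[int, int, int, int]:
    called = col != MISSING
    case = col[called & is_case]
    ctrl = col[called & ~is_case]
    case_alt = int(case.sum())
    ctrl_alt = int(ctrl.sum())
    return (case_alt, 2 * len(case) - case_alt, ctrl_alt, 2 * len(ctrl) - ctrl_alt)


def allelic_scan(
    G: GenotypeMatrix,
    status: np.ndarray,
    gc_variants: np.ndarray | None = None,
) -> tuple[list[AssocResult], InflationEstimate]:
    """Allelic test per variant + genomic-control and BH-FDR corrections.

    ``status`` is a boolean case indicator aligned with G.samples;
    ``gc_variants`` optionally restricts the lambda estimate to a subset
    (e.g. common variants).
    """
    is_case = np.asarray(status, dtype=bool)
    results = [
        allelic_test(*_allele_table(G.genotypes[:, j], is_case), variant_id=vid)
        for j, vid in enumerate(G.variants)
    ]
    if gc_variants is None:
        gc_chi2 = [r.chi2 for r in results if r.testable]
    else:
        keep = set(np.asarray(gc_variants))
        gc_chi2 = [r.chi2 for r in results if r.testable and r.variant_id in keep]
    inflation = genomic_control(gc_chi2)
    for r in results:
        if r.testable:
            r.p_gc = apply_genomic_control(r.chi2, inflation.lambda_)
    testable = [r for r in results if r.testable]
    if testable:
        adj = bh_fdr([r.p_gc for r in testable])
        for r, q in zip(testable, adj):
            r.p_fdr = float(q)
    return results, inflation


def cmh_scan(
    G: GenotypeMatrix, status: np.ndarray, strata: np.ndarray
) -> list[CmhResult]:
    """Per-variant CMH test with allele-count tables per stratum."""
    is_case = np.asarray(status, dtype=bool)
    strata = np.asarray(strata)
    labels = np.unique(strata)
    out = []
    for j, vid in enumerate(G.variants):
        col = G.genotypes[:, j]
        tables = [
            _allele_table(col[strata == st], is_case[strata == st]) for st in labels
        ]
        tables = [t for t in tables if sum(t) > 0]
        out.append(cmh_test(tables, id=vid))
    return out


def conditional_scan(
    G: GenotypeMatrix, status: np.ndarray, peak_variant: str
) -> list[CmhResult]:
    """Test every other variant stratified by the peak variant's genotype.

    Strata are the 0/1/2 genotype classes of the peak; variants monomorphic
    within every stratum come back flagged untestable.
    """
    is_case = np.asarray(status, dtype=bool)
    peak = G.column(peak_variant)
    classes = [g for g in (0, 1, 2) if (peak == g).sum() > 0]
    if len(classes) < 2:
        raise ValueError(f"peak variant {peak_variant!r} is monomorphic")
    out = []
    for j, vid in enumerate(G.variants):
        if vid == peak_variant:
            out.append(
                CmhResult(vid, [], float("nan"), float("nan"), float("nan"), False)
            )
            continue
        col = G.genotypes[:, j]
        tables = []
        for g in classes:
            mask = peak == g
            t = _allele_table(col[mask], is_case[mask])
            if sum(t) > 0:
                tables.append(t)
        res = cmh_test(tables, id=vid) if tables else CmhResult(
            vid, [], float("nan"), float("nan"), float("nan"), False
        )
        out.append(res)
    return out
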