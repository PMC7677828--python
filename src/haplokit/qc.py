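"""Sample and variant quality control.

Samples are excluded on call rate and mean fold coverage; variants get
minor-allele frequency, call rate and a Hardy-Weinberg test on control
genotypes, plus a frequency class and region density summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "SampleQc",
    "VariantStats",
    "filter_samples",
    "variant_stats",
    "hwe_test",
    "density_summary",
]

DEFAULT_MIN_CALL_RATE = 0.85
DEFAULT_MIN_DEPTH = 25.0
DEFAULT_COMMON_MAF = 0.05
DEFAULT_HWE_ALPHA = 1e-3


@dataclass
class SampleQc:
    sample_id: str
    call_rate: float
    mean_depth: float
    status: str  # "case" | "control"
    stratum: str
    sex: str = "U"

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"{self.sample_id}: call_rate outside [0, 1]")
        if self.mean_depth < 0:
            raise ValueError(f"{self.sample_id}: negative mean_depth")
        if self.status not in ("case", "control"):
            raise ValueError(f"{self.sample_id}: status must be case|control")


@dataclass
class VariantStats:
    variant_id: str
    position: int
    maf: float
    call_rate: float
    hwe_p_controls: float
    freq_class: str  # "common" | "low_frequency"
    annotation_flags: frozenset[str] = frozenset()
    alt_freq: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""


def filter_samples(
    qc: list[SampleQc],
    min_call_rate: float = DEFAULT_MIN_CALL_RATE,
    min_depth: float = DEFAULT_MIN_DEPTH,
) -> tuple[list[SampleQc], list[tuple[SampleQc, str]]]:
    """Partition samples into (retained, excluded-with-reason).

    Retention is inclusive on the good side: call_rate >= min_call_rate and
    mean_depth >= min_depth.
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate outside [0, 1]")
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    retained: list[SampleQc] = []
    excluded: list[tuple[SampleQc, str]] = []
    for s in qc:
        if s.call_rate < min_call_rate:
            excluded.append((s, "call_rate"))
        elif s.mean_depth < min_depth:
            excluded.append((s, "depth"))
        else:
            retained.append(s)
    return retained, excluded


def _hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg p by full enumeration of heterozygote counts
    conditional on allele counts (no mid-p)."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    # log P(het = h | n, n_minor) up to a shared constant
    def logprob(h: int) -> float:
        n_hom_minor = (n_minor - h) // 2
        n_hom_major = n - h - n_hom_minor
        return (
            h * math.log(2)
            - math.lgamma(n_hom_minor + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_hom_major + 1)
        )

    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = {h: logprob(h) for h in hets}
    mx = max(logs.values())
    probs = {h: math.exp(l - mx) for h, l in logs.items()}
    total = sum(probs.values())
    obs = probs[n_Aa]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``chi2``: Pearson 1-df test against expected proportions.
    ``exact``: full enumeration of heterozygote counts conditional on the
    allele counts; the p-value sums the probability of all tables at most as
    probable as the observed one.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be >= 0")
    if n_AA + n_Aa + n_aa == 0:
        raise ValueError("total genotype count is 0")
    if method == "chi2":
        return _hwe_chi2(n_AA, n_Aa, n_aa)[1]
    if method == "exact":
        return _hwe_exact(n_AA, n_Aa, n_aa)
    raise ValueError(f"unknown HWE method {method!r}")


def hwe_chi2_statistic(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Pearson HWE chi-square statistic (exposed for reporting)."""
    return _hwe_chi2(n_AA, n_Aa, n_aa)[0]


def variant_stats(
    G: GenotypeMatrix,
    samples: list[SampleQc],
    common_maf: float = DEFAULT_COMMON_MAF,
    hwe_method: str = "exact",
    hwe_per_stratum: bool = True,
    annotation_flags: dict[str, frozenset[str]] | None = None,
) -> list[VariantStats]:
    """Per-variant MAF, call rate, control HWE p and frequency class.

    MAF is computed over non-missing alleles and folded to <= 0.5.  HWE is
    tested on control genotypes only; with ``hwe_per_stratum`` the reported
    p is the minimum over strata (conservative screen), otherwise controls
    are pooled.  All-missing variants are flagged excluded.
    """
    by_id = {s.sample_id: s for s in samples}
    order = [by_id[s] for s in G.samples]
    is_control = np.array([s.status == "control" for s in order])
    strata = np.array([s.stratum for s in order])
    annotation_flags = annotation_flags or {}

    out: list[VariantStats] = []
    for j, vid in enumerate(G.variants):
        col = G.genotypes[:, j]
        called = col != MISSING
        call_rate = called.mean() if len(col) else 0.0
        if not called.any():
            out.append(
                VariantStats(
                    variant_id=vid,
                    position=int(G.positions[j]),
                    maf=float("nan"),
                    call_rate=0.0,
                    hwe_p_controls=1.0,
                    freq_class="low_frequency",
                    annotation_flags=annotation_flags.get(vid, frozenset()),
                    excluded=True,
                    exclusion_reason="all_missing",
                )
            )
            continue
        alt = col[called].astype(float).sum() / (2 * called.sum())
        maf = min(alt, 1.0 - alt)

        ctrl = col[is_control & called]
        if len(ctrl) == 0:
            hwe_p = 1.0
        elif hwe_per_stratum:
            ps = []
            for st in np.unique(strata):
                sub = col[is_control & called & (strata == st)]
                if len(sub):
                    ps.append(
                        hwe_test(
                            int((sub == 0).sum()),
                            int((sub == 1).sum()),
                            int((sub == 2).sum()),
                            method=hwe_method,
                        )
                    )
            hwe_p = min(ps) if ps else 1.0
        else:
            hwe_p = hwe_test(
                int((ctrl == 0).sum()),
                int((ctrl == 1).sum()),
                int((ctrl == 2).sum()),
                method=hwe_method,
            )
        out.append(
            VariantStats(
                variant_id=vid,
                position=int(G.positions[j]),
                maf=float(maf),
                call_rate=float(call_rate),
                hwe_p_controls=float(hwe_p),
                freq_class="common" if maf >= common_maf else "low_frequency",
                annotation_flags=annotation_flags.get(vid, frozenset()),
                alt_freq=float(alt),
            )
        )
    return out


def density_summary(stats_list: list[VariantStats], region_kb: float) -> dict:
    """Region-level variant summaries.

    Overall and common variants/kb rounded to one decimal; per-class counts;
    annotation-flag fractions as nearest-integer percent of all variants.
    """
    if region_kb <= 0:
        raise ValueError("region_kb must be > 0")
    usable = [s for s in stats_list if not s.excluded]
    n_total = len(usable)
    n_common = sum(1 for s in usable if s.freq_class == "common")
    flags: dict[str, int] = {}
    for s in usable:
        for f in s.annotation_flags:
            flags[f] = flags.get(f, 0) + 1
    flag_percent = (
        {f: int(round(100.0 * c / n_total)) for f, c in sorted(flags.items())}
        if n_total
        else {}
    )
    return {
        "n_total": n_total,
        "n_common": n_common,
        "n_low_frequency": n_total - n_common,
        "density_per_kb": round(n_total / region_kb, 1),
        "common_density_per_kb": round(n_common / region_kb, 1),
        "flag_percent": flag_percent,
    }


def variant_stats_frame(stats_list: list[VariantStats]) -> pd.DataFrame:
    """Tabular view for TSV export."""
    return pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in stats_list],
            "position": [s.position for s in stats_list],
            "maf": [s.maf for s in stats_list],
            "alt_freq": [s.alt_freq for s in stats_list],
            "call_rate": [s.call_rate for s in stats_list],
            "hwe_p_controls": [s.hwe_p_controls for s in stats_list],
            "freq_class": [s.freq_class for s in stats_list],
            "annotation_flags": [
                ",".join(sorted(s.annotation_flags)) for s in stats_list
            ],
            "excluded": [s.excluded for s in stats_list],
            "exclusion_reason": [s.exclusion_reason for s in stats_list],
        }
    )
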