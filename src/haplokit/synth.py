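"""Synthetic cohort generator.

Produces genotype, phenotype, expression and serology data with the
statistical structure the downstream analyses assume: a small number of
ancestral haplotypes at configurable stratum frequencies, retrospective
case-control sampling at exact per-haplotype odds ratios, an additive
cis-regulatory effect on a target gene, a reference-stable expression
background with planted differentially expressed genes, and antigen-specific
serology shifts in risk-homozygote carriers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "HaplotypePanel",
    "CohortSpec",
    "EqtlSpec",
    "make_default_panel",
    "case_frequencies",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_serology",
    "DEFAULT_STRATA",
]

#: default stratum sizes (cases, controls) mirroring a three-cohort design
DEFAULT_STRATA: dict[str, tuple[int, int]] = {
    "EA": (773, 576),
    "AA": (182, 181),
    "AS": (160, 160),
}

# default per-stratum haplotype frequencies; the protective haplotype is
# common in the first stratum and rarer elsewhere
_DEFAULT_FREQS: dict[str, dict[str, float]] = {
    "EA": {"HAP1": 0.55, "HAP2": 0.35, "HAP3": 0.10},
    "AA": {"HAP1": 0.20, "HAP2": 0.60, "HAP3": 0.20},
    "AS": {"HAP1": 0.30, "HAP2": 0.55, "HAP3": 0.15},
}


@dataclass
class HaplotypePanel:
    """Ordered haplotype bit-vectors with per-stratum frequencies."""

    n_sites: int
    haplotypes: list[tuple[str, np.ndarray]]
    freqs: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.haplotypes]
        if len(set(labels)) != len(labels):
            raise ValueError("haplotype labels must be unique")
        self.haplotypes = [
            (lab, np.asarray(vec, dtype=np.int8)) for lab, vec in self.haplotypes
        ]
        for lab, vec in self.haplotypes:
            if vec.shape != (self.n_sites,):
                raise ValueError(f"haplotype {lab} length != n_sites")
            if not np.isin(vec, (0, 1)).all():
                raise ValueError(f"haplotype {lab} is not a 0/1 vector")
        for stratum, f in self.freqs.items():
            if set(f) - set(labels):
                raise ValueError(f"stratum {stratum} names unknown haplotypes")
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"stratum {stratum} frequencies sum to {total}, not 1"
                )

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.haplotypes]

    def vector(self, label: str) -> np.ndarray:
        for lab, vec in self.haplotypes:
            if lab == label:
                return vec
        raise KeyError(label)


@dataclass
class CohortSpec:
    """Case-control sampling design.

    ``haplotype_log_or`` maps haplotype label to the log odds ratio of
    carrying that haplotype in cases vs controls; the reference haplotype
    (and any label omitted) has log OR 0.
    """

    strata: list[tuple[str, int, int]]
    haplotype_log_or: Mapping[str, float]
    reference: str = "HAP1"
    seed: int = 0
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, n_cases, n_controls in self.strata:
            if n_cases <= 0 or n_controls <= 0:
                raise ValueError(f"stratum {name}: counts must be > 0")
        if self.haplotype_log_or.get(self.reference, 0.0) != 0.0:
            raise ValueError("reference haplotype must have log OR 0")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")


@dataclass
class EqtlSpec:
    """Parameters of the simulated expression matrix."""

    n_genes: int = 1000
    effect_per_score: float = 1.0
    noise_sd: float = 0.5
    baseline: float = 10.0
    n_de_genes: int = 0
    de_fold: float = 2.0
    target_gene: str = "GENE_TARGET"
    background_mean: float = 10.0
    background_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")
        if self.de_fold <= 0:
            raise ValueError("de_fold must be > 0")
        if self.n_de_genes >= self.n_genes:
            raise ValueError("n_de_genes must leave room for background genes")


def make_default_panel(
    n_sites: int,
    n_hap2_diffs: int,
    freqs: Mapping[str, Mapping[str, float]] | None = None,
) -> HaplotypePanel:
    """Three nested haplotypes over ``n_sites`` biallelic positions.

    HAP1 is the all-reference vector, HAP3 the all-alternate vector, and
    HAP2 carries the alternate allele at the first ``n_hap2_diffs`` sites.
    Hamming distances are therefore d(HAP1, HAP3) = n_sites,
    d(HAP1, HAP2) = n_hap2_diffs and d(HAP2, HAP3) = n_sites - n_hap2_diffs.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    if not 0 < n_hap2_diffs <= n_sites:
        raise ValueError("n_hap2_diffs must be in (0, n_sites]")
    hap1 = np.zeros(n_sites, dtype=np.int8)
    hap3 = np.ones(n_sites, dtype=np.int8)
    hap2 = np.zeros(n_sites, dtype=np.int8)
    hap2[:n_hap2_diffs] = 1
    if freqs is None:
        freqs = _DEFAULT_FREQS
    freqs = {s: dict(f) for s, f in freqs.items()}
    return HaplotypePanel(
        n_sites=n_sites,
        haplotypes=[("HAP1", hap1), ("HAP2", hap2), ("HAP3", hap3)],
        freqs=freqs,
    )


def case_frequencies(
    control_freqs: Mapping[str, float],
    haplotype_log_or: Mapping[str, float],
    reference: str,
) -> dict[str, float]:
    """Case haplotype frequencies from control frequencies and per-haplotype
    log odds ratios.

    Each haplotype with a nonzero log OR has its carrier odds
    f/(1-f) multiplied by exp(log OR) and back-transformed; this makes the
    carrier-chromosome OR of that haplotype exact by construction.  The
    remaining haplotypes share the residual mass in proportion to their
    control frequencies.
    """
    transformed: dict[str, float] = {}
    base: dict[str, float] = {}
    for lab, f in control_freqs.items():
        log_or = float(haplotype_log_or.get(lab, 0.0))
        if lab != reference and log_or != 0.0:
            if f >= 1.0:
                warnings.warn(
                    f"haplotype {lab} is fixed in controls; OR has no effect"
                )
                transformed[lab] = f
                continue
            odds = f / (1.0 - f) * np.exp(log_or)
            transformed[lab] = odds / (1.0 + odds)
        else:
            base[lab] = f
    residual = 1.0 - sum(transformed.values())
    base_total = sum(base.values())
    if residual <= 0 or base_total <= 0:
        warnings.warn(
            "degenerate frequency vector: transformed haplotypes exhaust all "
            "mass; renormalizing jointly (ORs no longer exact)"
        )
        all_f = {**base, **transformed}
        total = sum(all_f.values())
        return {lab: f / total for lab, f in all_f.items()}
    out = dict(transformed)
    for lab, f in base.items():
        out[lab] = f * residual / base_total
    return out


def _draw_haplotypes(
    rng: np.random.Generator,
    labels: list[str],
    probs: np.ndarray,
    n_individuals: int,
) -> np.ndarray:
    return rng.choice(len(labels), size=(n_individuals, 2), p=probs)


def simulate_genotypes(
    panel: HaplotypePanel, spec: CohortSpec
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Retrospective case-control sampler.

    Controls draw two haplotypes from the stratum control frequencies; case
    frequencies are derived by the per-haplotype odds transform.  Genotype
    codes are the sum of the two drawn haplotypes' alleles at each site.

    Returns the genotype matrix, a sample sheet (sample_id, status, stratum,
    sex, call_rate, mean_depth) and a truth record with each individual's
    diplotype and the realized frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    labels = panel.labels
    vectors = np.stack([panel.vector(lab) for lab in labels])
    for lab in spec.haplotype_log_or:
        if lab not in labels:
            raise ValueError(f"log OR given for unknown haplotype {lab!r}")

    rows: list[dict] = []
    genotype_rows: list[np.ndarray] = []
    truth_diplotypes: dict[str, tuple[str, str]] = {}
    case_freq_record: dict[str, dict[str, float]] = {}

    counter = 0
    for stratum, n_cases, n_controls in spec.strata:
        if stratum not in panel.freqs:
            raise ValueError(f"panel has no frequencies for stratum {stratum!r}")
        ctrl_f = panel.freqs[stratum]
        case_f = case_frequencies(ctrl_f, spec.haplotype_log_or, spec.reference)
        case_freq_record[stratum] = case_f
        for status, n, fmap in (
            ("case", n_cases, case_f),
            ("control", n_controls, ctrl_f),
        ):
            probs = np.array([fmap.get(lab, 0.0) for lab in labels])
            probs = probs / probs.sum()
            draws = _draw_haplotypes(rng, labels, probs, n)
            haps = vectors[draws]  # (n, 2, n_sites)
            if spec.mutation_rate > 0:
                flips = rng.random(haps.shape) < spec.mutation_rate
                haps = np.where(flips, 1 - haps, haps)
            geno = haps.sum(axis=1).astype(np.int8)
            for i in range(n):
                counter += 1
                sid = f"S{counter:05d}"
                rows.append(
                    {
                        "sample_id": sid,
                        "status": status,
                        "stratum": stratum,
                        "sex": "F" if rng.random() < 0.9 else "M",
                        "call_rate": 1.0,
                        "mean_depth": float(np.round(rng.normal(150.0, 15.0), 1)),
                    }
                )
                truth_diplotypes[sid] = (labels[draws[i, 0]], labels[draws[i, 1]])
                genotype_rows.append(geno[i])

    sheet = pd.DataFrame(rows)
    variant_ids = [f"SNP{i + 1}" for i in range(panel.n_sites)]
    positions = _spread_positions(panel.n_sites)
    G = GenotypeMatrix(
        samples=sheet["sample_id"].tolist(),
        variants=variant_ids,
        positions=positions,
        genotypes=np.stack(genotype_rows),
    )
    truth = {
        "diplotypes": truth_diplotypes,
        "case_frequencies": case_freq_record,
        "control_frequencies": {s: dict(f) for s, f in panel.freqs.items()},
        "haplotype_log_or": dict(spec.haplotype_log_or),
        "reference": spec.reference,
        "seed": spec.seed,
    }
    return G, sheet, truth


def _spread_positions(
    n_sites: int, start: int = 10_678_000, end: int = 10_780_000
) -> np.ndarray:
    """Evenly spaced 1-based positions inside the target window."""
    return np.linspace(start + 1, end, n_sites, dtype=np.int64)


#: haplotype dose used for diplotype scores
HAPLOTYPE_SCORE = {"HAP1": 0, "HAP2": 1, "HAP3": 2}


def diplotype_score(pair: Sequence[str]) -> int:
    """Additive dose of a haplotype pair (HAP1=0, HAP2=1, HAP3=2 each)."""
    return sum(HAPLOTYPE_SCORE[h] for h in pair)


def simulate_expression(
    truth: dict,
    espec: EqtlSpec,
    seed: int | None = None,
    de_group: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Genes x samples RPKM-like matrix.

    The target gene decreases by ``effect_per_score`` per unit diplotype
    score from ``baseline``; ``n_de_genes`` background genes are shifted by
    ``de_fold`` in samples whose ``de_group`` label is "high"; the remaining
    genes share a common mean and variance (reference-stable pool).
    """
    diplotypes = truth["diplotypes"]
    samples = list(diplotypes)
    rng = np.random.default_rng(truth.get("seed", 0) + 1 if seed is None else seed)
    scores = np.array([diplotype_score(diplotypes[s]) for s in samples])

    n_bg = espec.n_genes - 1 - espec.n_de_genes
    genes = (
        [espec.target_gene]
        + [f"GENE_DE{i + 1}" for i in range(espec.n_de_genes)]
        + [f"GENE_BG{i + 1}" for i in range(n_bg)]
    )
    values = rng.normal(
        espec.background_mean, espec.background_sd, size=(len(genes), len(samples))
    )
    values[0] = (
        espec.baseline
        - espec.effect_per_score * scores
        + (rng.normal(0.0, espec.noise_sd, len(samples)) if espec.noise_sd > 0 else 0.0)
    )
    if espec.n_de_genes > 0:
        if de_group is None:
            raise ValueError("n_de_genes > 0 requires a de_group mapping")
        high = np.array([de_group.get(s) == "high" for s in samples])
        values[1 : 1 + espec.n_de_genes, high] *= espec.de_fold
    if (values < 0).any():
        warnings.warn("negative simulated expression clipped at 0")
        values = np.clip(values, 0.0, None)
    return pd.DataFrame(values, index=genes, columns=samples)


def simulate_serology(
    truth: dict,
    shift: Mapping[str, float],
    n_antigens: int = 90,
    seed: int | None = None,
    risk_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Antigens x samples fluorescence matrix with a ``__control__`` row.

    Background intensities are log-normal; antigens named in ``shift`` are
    multiplied by their shift factor in risk-diplotype carriers (default:
    HAP3/HAP3 homozygotes).  The control row models the per-array
    normalization channel.
    """
    diplotypes = truth["diplotypes"]
    samples = list(diplotypes)
    rng = np.random.default_rng(truth.get("seed", 0) + 2 if seed is None else seed)
    if risk_samples is None:
        risk_samples = [
            s for s, pair in diplotypes.items() if tuple(pair) == ("HAP3", "HAP3")
        ]
    risk = np.array([s in set(risk_samples) for s in samples])

    antigens = [f"AG{i + 1}" for i in range(n_antigens)]
    for a in shift:
        if a not in antigens:
            raise ValueError(f"shift names unknown antigen {a!r}")
    values = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=(n_antigens, len(samples)))
    for a, factor in shift.items():
        i = antigens.index(a)
        values[i, risk] *= factor
    control = rng.lognormal(mean=0.0, sigma=0.2, size=len(samples))
    out = pd.DataFrame(values, index=antigens, columns=samples)
    out.loc["__control__"] = control
    return out


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
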