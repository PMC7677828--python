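"""Haplotype estimation and haplotype-level association.

EM haplotype-frequency estimation over phase-compatible pairs from unphased
multilocus genotypes, pairwise linkage disequilibrium, D'-based tag-set
selection, per-haplotype stratified association and diplotype dose-effect
tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .assoc import AssocResult, CmhResult, allelic_test, cmh_test
from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "LDPair",
    "HaplotypeTable",
    "DiplotypeAssignment",
    "em_haplotype_frequencies",
    "ld_pair",
    "ld_from_genotypes",
    "select_tag_set",
    "haplotype_assoc",
    "assign_diplotypes",
    "diplotype_dose",
    "label_haplotypes",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000
EM_PRUNE = 1e-6
MAX_MISSING_FRAC = 0.2


@dataclass
class LDPair:
    variant_a: str
    variant_b: str
    D: float
    Dprime: float
    r2: float
    defined: bool = True


@dataclass
class HaplotypeTable:
    """EM output: haplotype strings with frequencies and expected counts."""

    sites: list[str]
    haplotypes: list[str]  # e.g. "0110..." strings
    freqs: np.ndarray
    expected_counts: np.ndarray
    n_samples: int
    log_likelihood: float
    n_iterations: int
    converged: bool
    low_confidence: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.haplotypes, self.freqs))


@dataclass
class DiplotypeAssignment:
    sample_id: str
    pair: tuple[str, str]  # haplotype labels, sorted
    posterior: float
    score: int


@lru_cache(maxsize=None)
def _compatible_pairs(genotype: tuple[int, ...]) -> tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]:
    """All unordered haplotype pairs compatible with a multilocus genotype.

    Missing sites (-1) are marginalized over all four allele combinations.
    """
    per_site: list[list[tuple[int, int]]] = []
    for g in genotype:
        if g == 0:
            per_site.append([(0, 0)])
        elif g == 2:
            per_site.append([(1, 1)])
        elif g == 1:
            per_site.append([(0, 1), (1, 0)])
        elif g == MISSING:
            per_site.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        else:
            raise ValueError(f"bad genotype code {g}")
    seen = set()
    out = []
    for combo in itertools.product(*per_site):
        h1 = tuple(a for a, _ in combo)
        h2 = tuple(b for _, b in combo)
        key = (h1, h2) if h1 <= h2 else (h2, h1)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return tuple(out)


def em_haplotype_frequencies(
    G: GenotypeMatrix,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    prune: float = EM_PRUNE,
    max_missing_frac: float = MAX_MISSING_FRAC,
) -> HaplotypeTable:
    """Maximum-likelihood haplotype frequencies by EM over phase pairs.

    The E step weights each compatible unordered pair (h1, h2) by
    f(h1) f(h2) (x2 when h1 != h2); the M step re-estimates frequencies from
    the expected haplotype counts.  Initial frequencies are products of
    single-site allele frequencies.  The log-likelihood is checked to be
    non-decreasing every iteration.
    """
    if G.n_variants > 25:
        raise ValueError("phase enumeration limited to <= 25 sites")
    geno = G.genotypes
    keep_sites = []
    for j in range(G.n_variants):
        if (geno[:, j] != MISSING).any():
            keep_sites.append(j)
        else:
            warnings.warn(f"site {G.variants[j]} all-missing; dropped from EM")
    geno = geno[:, keep_sites]
    sites = [G.variants[j] for j in keep_sites]
    n_sites = len(sites)
    if n_sites == 0:
        raise ValueError("no usable sites")

    missing_frac = (geno == MISSING).mean(axis=1)
    keep = missing_frac <= max_missing_frac
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} samples with >{max_missing_frac:.0%} missing "
            "tag genotypes excluded from haplotype analysis"
        )
    geno = geno[keep]
    n_samples = geno.shape[0]
    if n_samples == 0:
        raise ValueError("no samples left after missingness filter")

    # collapse identical genotype rows
    genotype_counts: dict[tuple[int, ...], int] = {}
    for row in geno:
        key = tuple(int(x) for x in row)
        genotype_counts[key] = genotype_counts.get(key, 0) + 1

    pair_lists = {g: _compatible_pairs(g) for g in genotype_counts}
    hap_set = sorted({h for pairs in pair_lists.values() for pair in pairs for h in pair})
    hap_index = {h: i for i, h in enumerate(hap_set)}
    n_haps = len(hap_set)
    H = np.array(hap_set, dtype=np.int8)

    # per genotype class: index arrays into hap_set plus het multiplicity
    classes = []
    for g, n_g in genotype_counts.items():
        pairs = pair_lists[g]
        i1 = np.fromiter((hap_index[p[0]] for p in pairs), dtype=np.int64, count=len(pairs))
        i2 = np.fromiter((hap_index[p[1]] for p in pairs), dtype=np.int64, count=len(pairs))
        mult = np.where(i1 == i2, 1.0, 2.0)
        classes.append((n_g, i1, i2, mult))

    # init: product of single-site allele frequencies over compatible set
    allele_freq = np.empty(n_sites)
    for j in range(n_sites):
        col = geno[:, j]
        called = col != MISSING
        allele_freq[j] = col[called].sum() / (2 * called.sum())
    p = np.clip(allele_freq, 1e-9, 1 - 1e-9)
    logf = H @ np.log(p) + (1 - H) @ np.log1p(-p)
    freqs = np.exp(logf - logf.max())
    freqs = np.clip(freqs, 1e-300, None)
    freqs /= freqs.sum()

    loglik_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(n_haps)
        loglik = 0.0
        for n_g, i1, i2, mult in classes:
            w = freqs[i1] * freqs[i2] * mult
            total = w.sum()
            if total <= 0:
                continue
            loglik += n_g * np.log(total)
            w *= n_g / total
            np.add.at(counts, i1, w)
            np.add.at(counts, i2, w)
        assert loglik >= loglik_prev - 1e-9, "EM likelihood decreased"
        new = counts / counts.sum()
        delta = np.abs(new - freqs).max()
        freqs = new
        loglik_prev = loglik
        if delta < tol:
            converged = True
            break

    expected = freqs * 2 * n_samples
    keep_h = freqs >= prune
    hap_strings = ["".join(map(str, h)) for h in hap_set]
    low_conf = not converged and it >= max_iter
    table = HaplotypeTable(
        sites=sites,
        haplotypes=[h for h, k in zip(hap_strings, keep_h) if k],
        freqs=freqs[keep_h],
        expected_counts=expected[keep_h],
        n_samples=n_samples,
        log_likelihood=float(loglik_prev),
        n_iterations=it,
        converged=converged,
        low_confidence=low_conf or _is_saddle(genotype_counts, n_sites),
    )
    return table


def _is_saddle(genotype_counts: dict, n_sites: int) -> bool:
    """True when every sample is heterozygous at every site (phase-flat)."""
    return all(all(g == 1 for g in key) for key in genotype_counts)


def ld_pair(
    f_ab: float, f_aB: float, f_Ab: float, f_AB: float,
    variant_a: str = "A", variant_b: str = "B",
) -> LDPair:
    """LD coefficients from two-site haplotype frequencies.

    Arguments are the frequencies of haplotypes ab, aB, Ab, AB where "A"/"B"
    denote the alternate alleles; they must sum to 1.
    """
    total = f_ab + f_aB + f_Ab + f_AB
    if abs(total - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    pA = f_AB + f_Ab
    pB = f_AB + f_aB
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDPair(variant_a, variant_b, 0.0, 0.0, 0.0, defined=False)
    D = f_AB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDPair(variant_a, variant_b, float(D), float(dprime), float(r2))


def ld_from_genotypes(G: GenotypeMatrix, variant_a: str, variant_b: str) -> LDPair:
    """Pairwise LD via two-site EM haplotype frequencies."""
    sub = G.subset_variants([variant_a, variant_b])
    table = em_haplotype_frequencies(sub)
    f = {h: 0.0 for h in ("00", "01", "10", "11")}
    f.update(table.as_dict())
    return ld_pair(f["00"], f["01"], f["10"], f["11"], variant_a, variant_b)


def select_tag_set(
    G: GenotypeMatrix, peak_variant: str, threshold: float = 0.8
) -> list[str]:
    """Variants whose D' with the peak is >= threshold, in positional order.

    The peak is always included (D' with itself is 1).
    """
    peak_col = G.column(peak_variant)
    called = peak_col[peak_col != MISSING]
    if len(np.unique(called)) < 2 and not (called == 1).any():
        raise ValueError(f"peak variant {peak_variant!r} is monomorphic")
    selected = []
    for vid in G.variants:
        if vid == peak_variant:
            selected.append(vid)
            continue
        ld = ld_from_genotypes(G, peak_variant, vid)
        if ld.defined and ld.Dprime >= threshold:
            selected.append(vid)
    order = {v: int(G.positions[G.variant_index(v)]) for v in selected}
    return sorted(selected, key=lambda v: order[v])


def label_haplotypes(
    haplotypes: list[str],
    panel_vectors: dict[str, np.ndarray],
    max_mismatch: int = 0,
) -> dict[str, str]:
    """Map haplotype strings to panel labels by Hamming-nearest match.

    Ties go to the lexicographically smallest label; haplotypes farther than
    ``max_mismatch`` from every panel vector are labeled OTHER.
    """
    out = {}
    for h in haplotypes:
        vec = np.array([int(c) for c in h])
        best_label, best_d = "OTHER", None
        for lab in sorted(panel_vectors):
            d = int((vec != panel_vectors[lab]).sum())
            if best_d is None or d < best_d:
                best_label, best_d = lab, d
        out[h] = best_label if best_d is not None and best_d <= max_mismatch else "OTHER"
    return out


def haplotype_assoc(
    G: GenotypeMatrix,
    status: np.ndarray,
    strata: np.ndarray,
    round_counts: bool = True,
) -> dict[str, tuple[CmhResult, dict[str, tuple]]]:
    """Per-haplotype stratified association from EM expected counts.

    For each haplotype seen in any stratum/group, a 2x2 table (this
    haplotype vs all others) of expected chromosome counts is built per
    stratum and combined with the CMH test.  Expected counts are rounded to
    the nearest integer by default (fractional mode via ``round_counts``).
    """
    status = np.asarray(status, dtype=bool)
    strata = np.asarray(strata)
    labels = list(dict.fromkeys(strata.tolist()))

    per_stratum: dict[str, dict[str, dict[str, float]]] = {}
    totals: dict[str, dict[str, float]] = {}
    all_haps: set[str] = set()
    for st in labels:
        per_stratum[st] = {}
        totals[st] = {}
        for grp, mask in (("case", status), ("control", ~status)):
            sel = (strata == st) & mask
            if sel.sum() == 0:
                continue
            sub = G.subset_samples([s for s, m in zip(G.samples, sel) if m])
            table = em_haplotype_frequencies(sub)
            counts = dict(zip(table.haplotypes, table.expected_counts))
            per_stratum[st][grp] = counts
            totals[st][grp] = 2.0 * table.n_samples
            all_haps.update(counts)

    results = {}
    for hap in sorted(all_haps):
        tables = []
        audit = {}
        for st in labels:
            if "case" not in per_stratum[st] or "control" not in per_stratum[st]:
                continue
            ca = per_stratum[st]["case"].get(hap, 0.0)
            co = per_stratum[st]["control"].get(hap, 0.0)
            ca_tot = totals[st]["case"]
            co_tot = totals[st]["control"]
            if round_counts:
                t = (
                    int(round(ca)),
                    int(round(ca_tot - ca)),
                    int(round(co)),
                    int(round(co_tot - co)),
                )
            else:
                t = (ca, ca_tot - ca, co, co_tot - co)
            audit[st] = t
            tables.append(t)
        results[hap] = (cmh_test(tables, id=hap), audit)
    return results


def assign_diplotypes(
    G: GenotypeMatrix,
    table: HaplotypeTable,
    panel_vectors: dict[str, np.ndarray] | None = None,
    score_map: dict[str, int] | None = None,
) -> list[DiplotypeAssignment]:
    """Maximum-posterior phase assignment from EM frequencies.

    Labels come from Hamming matching against ``panel_vectors`` when given,
    otherwise the raw haplotype strings are used.  Scores follow
    HAP1=0 / HAP2=1 / HAP3=2 summed over the pair; unlabeled haplotypes
    score 0 with a warning.
    """
    freqs = table.as_dict()
    if panel_vectors is not None:
        mapping = label_haplotypes(list(freqs), panel_vectors)
    else:
        mapping = {h: h for h in freqs}
    if score_map is None:
        score_map = {"HAP1": 0, "HAP2": 1, "HAP3": 2}

    # best phase is a function of the genotype class alone; cache it
    class_best: dict[tuple[int, ...], tuple[tuple[str, str], float] | None] = {}

    def _best_pair(g: tuple[int, ...]):
        if g in class_best:
            return class_best[g]
        best, best_w, total_w = None, 0.0, 0.0
        for h1, h2 in _compatible_pairs(g):
            s1, s2 = "".join(map(str, h1)), "".join(map(str, h2))
            f = freqs.get(s1, 0.0) * freqs.get(s2, 0.0)
            w = 2 * f if h1 != h2 else f
            total_w += w
            if w > best_w:
                best, best_w = (s1, s2), w
        res = (best, best_w / total_w) if best is not None and total_w > 0 else None
        class_best[g] = res
        return res

    out = []
    warned = False
    for i, sid in enumerate(G.samples):
        g = tuple(int(x) for x in G.genotypes[i])
        if (np.array(g) == MISSING).mean() > MAX_MISSING_FRAC:
            continue
        hit = _best_pair(g)
        if hit is None:
            continue
        best, posterior = hit
        lab = tuple(sorted(mapping.get(s, "OTHER") for s in best))
        score = 0
        for l in lab:
            if l in score_map:
                score += score_map[l]
            elif not warned:
                warnings.warn("unlabeled haplotype scored as 0 in diplotype dose")
                warned = True
        out.append(
            DiplotypeAssignment(
                sample_id=sid, pair=lab, posterior=posterior, score=score
            )
        )
    return out


def diplotype_dose(
    assignments: list[DiplotypeAssignment],
    status: dict[str, bool],
    reference: tuple[str, str] = ("HAP1", "HAP1"),
) -> dict:
    """Per-diplotype odds ratios against a reference diplotype plus a
    linear dose-trend of status on the diplotype score.
    """
    reference = tuple(sorted(reference))
    counts: dict[tuple[str, str], list[int]] = {}
    for a in assignments:
        is_case = status[a.sample_id]
        c = counts.setdefault(a.pair, [0, 0])
        c[0 if is_case else 1] += 1
    if reference not in counts or min(counts[reference]) == 0:
        raise ValueError(
            f"reference diplotype {reference} absent from cases or controls"
        )
    ref_case, ref_ctrl = counts[reference]
    per_diplotype: dict[tuple[str, str], AssocResult] = {}
    for pair, (n_case, n_ctrl) in counts.items():
        if pair == reference:
            continue
        per_diplotype[pair] = allelic_test(
            n_case, ref_case, n_ctrl, ref_ctrl, variant_id="/".join(pair)
        )
    scores = np.array([a.score for a in assignments], dtype=float)
    y = np.array([1.0 if status[a.sample_id] else 0.0 for a in assignments])
    if len(np.unique(scores)) >= 2:
        reg = stats.linregress(scores, y)
        trend = {"slope": float(reg.slope), "p": float(reg.pvalue)}
    else:
        trend = {"slope": float("nan"), "p": float("nan")}
    return {"per_diplotype": per_diplotype, "trend": trend, "counts": counts}
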