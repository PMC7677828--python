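import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplokit.haplo import (
    DiplotypeAssignment,
    assign_diplotypes,
    diplotype_dose,
    em_haplotype_frequencies,
    haplotype_assoc,
    label_haplotypes,
    ld_from_genotypes,
    ld_pair,
    select_tag_set,
)
from haplokit.synth import CohortSpec, make_default_panel, simulate_genotypes
from tests.conftest import genotype_matrix


def brute_force_2site_loglik(genotype_rows, f):
    """Log-likelihood of two-site genotype data under haplotype
    frequencies f = (f00, f01, f10, f11); independent oracle."""
    haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
    ll = 0.0
    for g in genotype_rows:
        p = 0.0
        for i, h1 in enumerate(haps):
            for j, h2 in enumerate(haps):
                if (h1[0] + h2[0], h1[1] + h2[1]) == tuple(g):
                    p += f[i] * f[j]
        if p <= 0:
            return -np.inf
        ll += np.log(p)
    return ll


def brute_force_2site_mle(genotype_rows, step=0.01):
    best, best_ll = None, -np.inf
    grid = np.arange(0, 1 + step / 2, step)
    for f00 in grid:
        for f01 in grid:
            if f00 + f01 > 1 + 1e-12:
                break
            for f10 in grid:
                f11 = 1 - f00 - f01 - f10
                if f11 < -1e-12:
                    break
                f = (f00, f01, f10, max(f11, 0.0))
                ll = brute_force_2site_loglik(genotype_rows, f)
                if ll > best_ll:
                    best, best_ll = f, ll
    return best, best_ll


class TestEmHaplotypeFrequencies:
    def test_homozygous_samples_equal_counting(self):
        # phases unambiguous: frequencies are direct haplotype counts
        G = genotype_matrix([[0, 0], [0, 0], [2, 2], [0, 2]])
        t = em_haplotype_frequencies(G)
        f = t.as_dict()
        # haplotypes: 00 x4 (s0, s1), 11 x2 (s2), 01 x2 (s3)
        assert f["00"] == pytest.approx(4 / 8)
        assert f["11"] == pytest.approx(2 / 8)
        assert f["01"] == pytest.approx(2 / 8)

    def test_coupling_fixed_point(self):
        # {AABB, aabb, AaBb} -> f(AB) = f(ab) = 0.5
        G = genotype_matrix([[0, 0], [2, 2], [1, 1]])
        t = em_haplotype_frequencies(G)
        f = t.as_dict()
        assert f.get("00", 0) == pytest.approx(0.5, abs=1e-6)
        assert f.get("11", 0) == pytest.approx(0.5, abs=1e-6)
        assert f.get("01", 0) == pytest.approx(0.0, abs=1e-6)
        assert f.get("10", 0) == pytest.approx(0.0, abs=1e-6)

    def test_all_double_het_saddle(self):
        G = genotype_matrix([[1, 1], [1, 1], [1, 1]])
        t = em_haplotype_frequencies(G)
        assert t.low_confidence
        for v in t.as_dict().values():
            assert v == pytest.approx(0.25, abs=1e-6)

    @pytest.mark.parametrize(
        "rows",
        [
            [[0, 0], [1, 1]],
            [[0, 1], [1, 0], [2, 2]],
            [[1, 1], [0, 2], [2, 0], [1, 1]],
            [[0, 0], [0, 1], [1, 0], [1, 1], [2, 2]],
            [[2, 1], [1, 2], [0, 0]],
            [[1, 0], [1, 2], [0, 1], [2, 1], [1, 1], [0, 0]],
        ],
    )
    def test_em_matches_brute_force_grid(self, rows):
        G = genotype_matrix(rows)
        t = em_haplotype_frequencies(G)
        f = {h: 0.0 for h in ("00", "01", "10", "11")}
        f.update(t.as_dict())
        em_ll = brute_force_2site_loglik(
            rows, (f["00"], f["01"], f["10"], f["11"])
        )
        _, grid_ll = brute_force_2site_mle(rows)
        # the EM optimum must be at least as good as the 0.01-grid optimum
        assert em_ll >= grid_ll - 1e-6

    def test_expected_counts_sum(self):
        G = genotype_matrix([[0, 1], [1, 1], [2, 2], [1, 0]])
        t = em_haplotype_frequencies(G, prune=0.0)
        assert t.expected_counts.sum() == pytest.approx(2 * t.n_samples)

    def test_all_missing_site_dropped(self):
        G = genotype_matrix([[0, -1], [1, -1], [2, -1]])
        with pytest.warns(UserWarning, match="all-missing"):
            t = em_haplotype_frequencies(G)
        assert t.sites == ["v0"]

    def test_high_missingness_sample_excluded(self):
        rows = [[0, 0, 0, 0], [1, 1, 0, 0], [-1, -1, -1, 0]]
        G = genotype_matrix(rows)
        with pytest.warns(UserWarning, match="missing"):
            t = em_haplotype_frequencies(G)
        assert t.n_samples == 2

    def test_too_many_sites_rejected(self):
        G = genotype_matrix([[0] * 26])
        with pytest.raises(ValueError, match="25"):
            em_haplotype_frequencies(G)


class TestLdPair:
    def test_perfect_coupling(self):
        ld = ld_pair(0.5, 0.0, 0.0, 0.5)
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_independence(self):
        # f(AB) = pA pB with pA = 0.5, pB = 0.4
        ld = ld_pair(0.3, 0.2, 0.3, 0.2)
        assert ld.Dprime == pytest.approx(0.0, abs=1e-12)
        assert ld.r2 == pytest.approx(0.0, abs=1e-12)

    def test_closed_form(self):
        ld = ld_pair(0.4, 0.1, 0.1, 0.4)
        assert ld.D == pytest.approx(0.15)
        assert ld.Dprime == pytest.approx(0.6)
        assert ld.r2 == pytest.approx(0.36)

    def test_monomorphic_undefined(self):
        ld = ld_pair(0.5, 0.0, 0.5, 0.0)  # pB = 0
        assert not ld.defined

    @given(
        f=st.tuples(*(st.floats(0.01, 1.0) for _ in range(4))),
    )
    def test_relabel_invariance(self, f):
        total = sum(f)
        f00, f01, f10, f11 = (x / total for x in f)
        a = ld_pair(f00, f01, f10, f11)
        # relabel both sites: ab <-> AB, aB <-> Ab
        b = ld_pair(f11, f10, f01, f00)
        assert b.Dprime == pytest.approx(a.Dprime, abs=1e-9)
        assert b.r2 == pytest.approx(a.r2, abs=1e-9)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError):
            ld_pair(0.5, 0.5, 0.5, 0.5)


class TestSelectTagSet:
    def test_panel_cohort_selects_all_sites(self, small_cohort):
        G, sheet, truth = small_cohort
        tags = select_tag_set(G, "SNP1", threshold=0.8)
        assert tags == G.variants  # three-haplotype construction: D' = 1

    def test_unreachable_threshold_keeps_peak(self, small_cohort):
        G, _, _ = small_cohort
        tags = select_tag_set(G, "SNP1", threshold=1.01)
        assert tags == ["SNP1"]

    def test_positional_order(self, small_cohort):
        G, _, _ = small_cohort
        tags = select_tag_set(G, "SNP3", threshold=0.8)
        positions = [G.positions[G.variant_index(v)] for v in tags]
        assert positions == sorted(positions)


class TestLabelHaplotypes:
    def test_exact_and_other(self):
        panel = {"HAP1": np.array([0, 0]), "HAP3": np.array([1, 1])}
        out = label_haplotypes(["00", "11", "01"], panel)
        assert out == {"00": "HAP1", "11": "HAP3", "01": "OTHER"}

    def test_nearest_with_mismatch_budget(self):
        panel = {"HAP1": np.array([0, 0, 0]), "HAP3": np.array([1, 1, 1])}
        out = label_haplotypes(["100"], panel, max_mismatch=1)
        assert out["100"] == "HAP1"

    def test_tie_lexicographic(self):
        panel = {"B": np.array([1, 1]), "A": np.array([0, 0])}
        out = label_haplotypes(["01"], panel, max_mismatch=1)
        assert out["01"] == "A"


class TestHaplotypeAssoc:
    def test_null_recovery(self, small_panel):
        spec = CohortSpec(strata=[("EA", 2000, 2000)], haplotype_log_or={}, seed=21)
        G, sheet, truth = simulate_genotypes(small_panel, spec)
        status = (sheet["status"] == "case").to_numpy()
        strata = sheet["stratum"].to_numpy()
        res = haplotype_assoc(G, status, strata)
        # common haplotype (freq 0.55): tight null window
        cmh1, _ = res["0" * 5]
        assert 0.9 < cmh1.or_mh < 1.1
        # every haplotype within a 2.5-SE null window at this sample size
        for hap in ("0" * 5, "111" + "00", "1" * 5):
            cmh, _ = res[hap]
            assert 0.8 < cmh.or_mh < 1.25

    def test_single_stratum_reduces_to_allelic(self):
        from haplokit.assoc import allelic_test

        G = genotype_matrix([[0], [2], [1], [0], [2], [2]])
        status = np.array([True, True, True, False, False, False])
        strata = np.array(["EA"] * 6)
        res = haplotype_assoc(G, status, strata)
        cmh, audit = res["1"]
        t = audit["EA"]
        assert cmh.or_mh == pytest.approx(allelic_test(*t).or_)


class TestDiplotypeDose:
    def _assignments(self, spec_counts):
        out, status = [], {}
        i = 0
        for pair, (n_case, n_ctrl) in spec_counts.items():
            for is_case, n in ((True, n_case), (False, n_ctrl)):
                for _ in range(n):
                    sid = f"s{i}"
                    i += 1
                    score = sum({"HAP1": 0, "HAP2": 1, "HAP3": 2}[h] for h in pair)
                    out.append(DiplotypeAssignment(sid, pair, 1.0, score))
                    status[sid] = is_case
        return out, status

    def test_printed_or(self):
        assignments, status = self._assignments(
            {("HAP1", "HAP1"): (400, 400), ("HAP3", "HAP3"): (34, 20)}
        )
        res = diplotype_dose(assignments, status)
        r = res["per_diplotype"][("HAP3", "HAP3")]
        assert r.or_ == pytest.approx(1.7)

    def test_multiplicative_ordering(self, small_panel):
        spec = CohortSpec(
            strata=[("EA", 4000, 4000)],
            haplotype_log_or={"HAP3": np.log(1.5)},
            seed=7,
        )
        G, sheet, truth = simulate_genotypes(small_panel, spec)
        status = dict(zip(sheet["sample_id"], sheet["status"] == "case"))
        table = em_haplotype_frequencies(G)
        pv = {lab: small_panel.vector(lab) for lab in small_panel.labels}
        assignments = assign_diplotypes(G, table, panel_vectors=pv)
        res = diplotype_dose(assignments, status)
        or33 = res["per_diplotype"][("HAP3", "HAP3")].or_
        or13 = res["per_diplotype"][("HAP1", "HAP3")].or_
        assert or33 > or13 > 1.0
        assert res["trend"]["slope"] > 0

    def test_missing_reference_rejected(self):
        assignments, status = self._assignments({("HAP3", "HAP3"): (5, 5)})
        with pytest.raises(ValueError, match="reference"):
            diplotype_dose(assignments, status)

    def test_all_reference_no_testable_diplotypes(self):
        assignments, status = self._assignments({("HAP1", "HAP1"): (5, 5)})
        res = diplotype_dose(assignments, status)
        assert res["per_diplotype"] == {}


class TestEmLikelihoodMonotone:
    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_em_runs_on_random_small_instances(self, seed):
        # the non-decreasing likelihood assertion inside the EM loop fires
        # if monotonicity is ever violated
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 3, size=(rng.integers(2, 12), rng.integers(1, 4)))
        t = em_haplotype_frequencies(genotype_matrix(rows), prune=0.0)
        assert t.expected_counts.sum() == pytest.approx(2 * t.n_samples)
        assert t.freqs.sum() == pytest.approx(1.0)
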