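import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplokit.synth import (
    CohortSpec,
    EqtlSpec,
    case_frequencies,
    diplotype_score,
    make_default_panel,
    simulate_expression,
    simulate_genotypes,
    simulate_serology,
)


def hamming(a, b):
    return int((a != b).sum())


class TestMakeDefaultPanel:
    def test_distances_19_15(self):
        p = make_default_panel(19, 15)
        h1, h2, h3 = (p.vector(lab) for lab in ("HAP1", "HAP2", "HAP3"))
        assert hamming(h1, h3) == 19
        assert hamming(h1, h2) == 15
        assert hamming(h2, h3) == 4

    def test_degenerate_single_site(self):
        p = make_default_panel(1, 1)
        assert np.array_equal(p.vector("HAP2"), p.vector("HAP3"))

    @given(
        n=st.integers(min_value=1, max_value=30),
        data=st.data(),
    )
    def test_nested_distances_additive(self, n, data):
        k = data.draw(st.integers(min_value=1, max_value=n))
        p = make_default_panel(n, k)
        h1, h2, h3 = (p.vector(lab) for lab in ("HAP1", "HAP2", "HAP3"))
        assert hamming(h1, h2) + hamming(h2, h3) == hamming(h1, h3)

    @pytest.mark.parametrize("n,k", [(0, 0), (5, 0), (5, 6), (-1, 1)])
    def test_invalid_counts(self, n, k):
        with pytest.raises(ValueError):
            make_default_panel(n, k)

    def test_frequencies_sum_to_one(self):
        p = make_default_panel(19, 15)
        for f in p.freqs.values():
            assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)


class TestCaseFrequencies:
    def test_odds_transform_example(self):
        # control odds 0.1111 x 1.5 = 0.1667 -> frequency 1/7
        f = case_frequencies(
            {"HAP1": 0.6, "HAP2": 0.3, "HAP3": 0.1},
            {"HAP3": np.log(1.5)},
            "HAP1",
        )
        assert f["HAP3"] == pytest.approx(1 / 7, abs=1e-12)
        assert sum(f.values()) == pytest.approx(1.0)

    def test_null_is_identity(self):
        ctrl = {"HAP1": 0.6, "HAP2": 0.3, "HAP3": 0.1}
        assert case_frequencies(ctrl, {}, "HAP1") == pytest.approx(ctrl)

    @given(
        f3=st.floats(min_value=0.01, max_value=0.6),
        log_or=st.floats(min_value=-1.5, max_value=1.5),
    )
    def test_carrier_or_exact(self, f3, log_or):
        ctrl = {"HAP1": (1 - f3) * 0.7, "HAP2": (1 - f3) * 0.3, "HAP3": f3}
        case = case_frequencies(ctrl, {"HAP3": log_or}, "HAP1")
        case_odds = case["HAP3"] / (1 - case["HAP3"])
        ctrl_odds = f3 / (1 - f3)
        assert np.log(case_odds / ctrl_odds) == pytest.approx(log_or, abs=1e-9)

    def test_degenerate_warns(self):
        with pytest.warns(UserWarning):
            case_frequencies({"HAP3": 1.0, "HAP1": 0.0}, {"HAP3": 0.5}, "HAP1")


class TestSimulateGenotypes:
    def test_null_model_frequencies_agree(self, small_panel):
        n = 10_000
        spec = CohortSpec(strata=[("EA", n, n)], haplotype_log_or={}, seed=3)
        G, sheet, truth = simulate_genotypes(small_panel, spec)
        dip = truth["diplotypes"]
        status = dict(zip(sheet["sample_id"], sheet["status"]))
        for hap in ("HAP1", "HAP2", "HAP3"):
            freq = {}
            for grp in ("case", "control"):
                ids = [s for s in dip if status[s] == grp]
                count = sum(list(dip[s]).count(hap) for s in ids)
                freq[grp] = count / (2 * len(ids))
            f = small_panel.freqs["EA"][hap]
            se = np.sqrt(f * (1 - f) / (2 * n))
            assert abs(freq["case"] - freq["control"]) < 3 * np.sqrt(2) * se

    def test_planted_or_case_frequency(self, small_panel):
        # control HAP3 freq 0.10 with OR 1.5 -> case freq ~ 1/7
        panel = make_default_panel(
            5, 3, freqs={"EA": {"HAP1": 0.6, "HAP2": 0.3, "HAP3": 0.1}}
        )
        n = 5_000
        spec = CohortSpec(
            strata=[("EA", n, n)], haplotype_log_or={"HAP3": np.log(1.5)}, seed=5
        )
        G, sheet, truth = simulate_genotypes(panel, spec)
        status = dict(zip(sheet["sample_id"], sheet["status"]))
        dip = truth["diplotypes"]
        case_ids = [s for s in dip if status[s] == "case"]
        freq = sum(list(dip[s]).count("HAP3") for s in case_ids) / (2 * n)
        assert freq == pytest.approx(1 / 7, abs=3 * np.sqrt((1 / 7) * (6 / 7) / (2 * n)))

    def test_determinism(self, small_panel):
        spec = CohortSpec(strata=[("EA", 50, 50)], haplotype_log_or={}, seed=9)
        G1, sheet1, t1 = simulate_genotypes(small_panel, spec)
        G2, sheet2, t2 = simulate_genotypes(small_panel, spec)
        assert np.array_equal(G1.genotypes, G2.genotypes)
        assert sheet1.equals(sheet2)
        assert t1["diplotypes"] == t2["diplotypes"]

    def test_genotype_is_sum_of_drawn_haplotypes(self, small_cohort, small_panel):
        G, sheet, truth = small_cohort
        for i, sid in enumerate(G.samples):
            h1, h2 = truth["diplotypes"][sid]
            expected = small_panel.vector(h1) + small_panel.vector(h2)
            assert np.array_equal(G.genotypes[i], expected)

    def test_unknown_or_label_rejected(self, small_panel):
        spec = CohortSpec(strata=[("EA", 5, 5)], haplotype_log_or={"NOPE": 0.2}, seed=0)
        with pytest.raises(ValueError, match="NOPE"):
            simulate_genotypes(small_panel, spec)


class TestSimulateExpression:
    def _truth(self, pairs):
        return {"diplotypes": {f"s{i}": p for i, p in enumerate(pairs)}, "seed": 0}

    def test_noiseless_forty_percent_reduction(self):
        truth = self._truth([("HAP1", "HAP1"), ("HAP3", "HAP3")])
        espec = EqtlSpec(n_genes=5, effect_per_score=1.0, noise_sd=0.0, baseline=10.0)
        M = simulate_expression(truth, espec)
        target = M.loc[espec.target_gene]
        assert target["s0"] == pytest.approx(10.0)
        assert target["s1"] == pytest.approx(6.0)  # 40% lower

    def test_zero_effect_is_flat(self):
        pairs = [("HAP1", "HAP1"), ("HAP2", "HAP3"), ("HAP3", "HAP3")] * 30
        truth = self._truth(pairs)
        espec = EqtlSpec(n_genes=5, effect_per_score=0.0, noise_sd=0.3)
        M = simulate_expression(truth, espec)
        scores = [diplotype_score(p) for p in pairs]
        slope = np.polyfit(scores, M.loc[espec.target_gene].to_numpy(), 1)[0]
        assert abs(slope) < 0.2

    def test_de_fold_ratio(self):
        pairs = [("HAP1", "HAP1")] * 40
        truth = self._truth(pairs)
        group = {f"s{i}": ("high" if i < 20 else "low") for i in range(40)}
        espec = EqtlSpec(n_genes=10, n_de_genes=2, de_fold=2.0, noise_sd=0.0,
                         background_sd=0.05)
        M = simulate_expression(truth, espec, de_group=group)
        hi = [s for s, g in group.items() if g == "high"]
        lo = [s for s, g in group.items() if g == "low"]
        ratio = M.loc["GENE_DE1", hi].mean() / M.loc["GENE_DE1", lo].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_negative_clip_warns(self):
        truth = self._truth([("HAP3", "HAP3")] * 4)
        espec = EqtlSpec(n_genes=3, effect_per_score=5.0, baseline=1.0, noise_sd=0.0)
        with pytest.warns(UserWarning, match="clip"):
            M = simulate_expression(truth, espec)
        assert (M.to_numpy() >= 0).all()


class TestSimulateSerology:
    def _truth(self):
        pairs = [("HAP3", "HAP3")] * 20 + [("HAP1", "HAP1")] * 20
        return {"diplotypes": {f"s{i}": p for i, p in enumerate(pairs)}, "seed": 1}

    def test_no_shift_equal_means(self):
        truth = self._truth()
        M = simulate_serology(truth, shift={"AG1": 1.0}, n_antigens=10)
        risk = [f"s{i}" for i in range(20)]
        prot = [f"s{i}" for i in range(20, 40)]
        ratio = M.loc["AG1", risk].mean() / M.loc["AG1", prot].mean()
        assert 0.5 < ratio < 2.0

    def test_shift_applied_to_risk_group(self):
        truth = self._truth()
        M = simulate_serology(truth, shift={"AG1": 6.0}, n_antigens=10)
        risk = [f"s{i}" for i in range(20)]
        prot = [f"s{i}" for i in range(20, 40)]
        ratio = M.loc["AG1", risk].mean() / M.loc["AG1", prot].mean()
        assert ratio > 3.0

    def test_reproducible_and_has_control_row(self):
        truth = self._truth()
        M1 = simulate_serology(truth, shift={}, n_antigens=5)
        M2 = simulate_serology(truth, shift={}, n_antigens=5)
        pd.testing.assert_frame_equal(M1, M2)
        assert "__control__" in M1.index

    def test_unknown_antigen_rejected(self):
        with pytest.raises(ValueError, match="AGX"):
            simulate_serology(self._truth(), shift={"AGX": 2.0}, n_antigens=3)
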