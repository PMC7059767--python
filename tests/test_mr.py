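import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmediate.datatypes import LDMatrix
from methmediate.mr import (
    MendelianRandomization,
    egger,
    harmonize,
    ivw,
    max_likelihood,
    prune_ld,
    reverse_mr_2sls,
    select_mediators,
    steiger_locus_orientation,
    wald_ratio,
    weighted_median,
    MRResult,
)
from tests.conftest import make_summary_stats


def exposure_frame(snps, b_zx, se_zx=0.05, p_zx=1e-8, effect="A", other="G"):
    k = len(snps)
    df = pd.DataFrame({
        "snp": snps,
        "b_zx": np.asarray(b_zx, dtype=float),
        "se_zx": np.broadcast_to(np.asarray(se_zx, float), (k,)).copy(),
        "p": np.broadcast_to(np.asarray(p_zx, float), (k,)).copy(),
        "effect_allele": effect if isinstance(effect, list) else [effect] * k,
        "other_allele": other if isinstance(other, list) else [other] * k,
    })
    df["p_zx"] = df["p"]  # harmonized-frame name, for direct estimator calls
    return df


class TestHarmonize:
    def test_matching_swapped_and_strand_flip(self):
        exp = exposure_frame(["s1", "s2", "s3"], [0.5, 0.5, 0.5],
                             effect=["A", "A", "A"], other=["G", "G", "G"])
        out = make_summary_stats(
            ["s1", "s2", "s3"], [0.2, 0.2, 0.2], 0.05,
            effect=["A", "G", "T"], other=["G", "A", "C"])
        # s1 matches; s2 swapped alleles -> sign flip; s3 is the reverse
        # strand (A/G complements to T/C) -> matches after complementing
        h = harmonize(exp, out)
        by = h.set_index("snp")["b_zy"]
        assert by["s1"] == pytest.approx(0.2)
        assert by["s2"] == pytest.approx(-0.2)
        assert by["s3"] == pytest.approx(0.2)

    def test_palindromic_dropped_only_in_eaf_window(self):
        exp = exposure_frame(["p1", "p2"], [0.5, 0.5],
                             effect=["A", "A"], other=["T", "T"])
        out = make_summary_stats(["p1", "p2"], [0.2, 0.2], 0.05,
                                 eaf=[0.5, 0.9],
                                 effect=["A", "A"], other=["T", "T"])
        h = harmonize(exp, out)
        assert "p1" not in set(h["snp"])  # ambiguous EAF 0.5
        assert "p2" in set(h["snp"])      # EAF 0.9 resolves strand

    def test_irreconcilable_alleles_dropped(self):
        exp = exposure_frame(["s1"], [0.5], effect=["A"], other=["G"])
        out = make_summary_stats(["s1"], [0.2], 0.05, effect=["A"], other=["C"])
        assert len(harmonize(exp, out)) == 0


class TestPruneLD:
    def test_greedy_keeps_best_p_per_clump(self):
        inst = exposure_frame(["a", "b", "c"], [0.5, 0.5, 0.5],
                              p_zx=[1e-10, 1e-8, 1e-6])
        r = np.array([[1.0, 0.7, 0.1],
                      [0.7, 1.0, 0.1],
                      [0.1, 0.1, 1.0]])
        ld = LDMatrix(["a", "b", "c"], r)
        kept = prune_ld(inst, ld, r2_max=0.2)
        # b is pruned by a (r^2 = 0.49 >= 0.2); c survives (r^2 = 0.01)
        assert list(kept["snp"]) == ["a", "c"]

    def test_tie_break_is_deterministic(self):
        inst = exposure_frame(["b", "a"], [0.5, 0.5], p_zx=[1e-8, 1e-8])
        ld = LDMatrix(["b", "a"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        kept = prune_ld(inst, ld, r2_max=0.2,
                        positions={"a": 100, "b": 200})
        assert list(kept["snp"]) == ["a"]  # equal p -> smaller position wins


class TestEstimators:
    def test_wald_ratio_first_and_second_order(self):
        inst = pd.Series({"snp": "s", "b_zx": 0.4, "se_zx": 0.08,
                          "b_zy": 0.2, "se_zy": 0.05})
        r1 = wald_ratio(inst)
        assert r1.b_xy == pytest.approx(0.5)
        assert r1.se == pytest.approx(0.05 / 0.4)
        r2 = wald_ratio(inst, second_order=True)
        se2 = np.sqrt(0.05**2 / 0.4**2 + 0.2**2 * 0.08**2 / 0.4**4)
        assert r2.se == pytest.approx(se2)
        assert r2.se > r1.se

    def test_ivw_hand_computation(self):
        inst = pd.DataFrame({
            "snp": ["s1", "s2"],
            "b_zx": [1.0, 1.0], "se_zx": [0.01, 0.01],
            "b_zy": [0.2, 0.4], "se_zy": [0.1, 0.1],
            "p_zx": [1e-9, 1e-8],
        })
        fe = ivw(inst, "fixed")
        # w = 100 each: b = (0.2+0.4)/2 = 0.3, se = 1/sqrt(200)
        assert fe.b_xy == pytest.approx(0.3)
        assert fe.se == pytest.approx(np.sqrt(1.0 / 200.0))
        assert fe.top_snp == "s1"
        mre = ivw(inst, "mre")
        # Q = 100*0.01 + 100*0.01 = 2; scale sqrt(max(1, 2/1))
        assert mre.b_xy == pytest.approx(0.3)
        assert mre.se == pytest.approx(np.sqrt(1.0 / 200.0) * np.sqrt(2.0))

    def test_ivw_needs_two_instruments(self):
        inst = pd.DataFrame({"snp": ["s1"], "b_zx": [1.0], "se_zx": [0.01],
                             "b_zy": [0.2], "se_zy": [0.1]})
        with pytest.raises(ValueError):
            ivw(inst)

    def test_egger_recovers_line(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        inst = pd.DataFrame({
            "snp": [f"s{i}" for i in range(4)],
            "b_zx": bx, "se_zx": 0.01,
            "b_zy": 0.1 + 0.5 * bx, "se_zy": 0.05,
        })
        res = egger(inst)
        assert res.b_xy == pytest.approx(0.5, abs=1e-9)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-9)

    def test_egger_needs_three_instruments(self):
        inst = pd.DataFrame({"snp": ["a", "b"], "b_zx": [0.2, 0.4],
                             "se_zx": 0.01, "b_zy": [0.1, 0.2], "se_zy": 0.05})
        assert egger(inst).is_na()

    def test_weighted_median_on_consistent_ratios(self):
        inst = pd.DataFrame({
            "snp": ["a", "b", "c"],
            "b_zx": [0.2, 0.4, 0.6], "se_zx": 0.01,
            "b_zy": [0.1, 0.2, 0.3], "se_zy": 0.05,
        })
        res = weighted_median(inst, n_boot=200, seed=1)
        assert res.b_xy == pytest.approx(0.5, abs=1e-6)

    def test_max_likelihood_matches_ivw_with_exact_exposure(self):
        inst = pd.DataFrame({
            "snp": ["a", "b", "c"],
            "b_zx": [0.3, 0.5, 0.8], "se_zx": 1e-8,
            "b_zy": [0.09, 0.15, 0.24], "se_zy": 0.05,
        })
        res = max_likelihood(inst)
        assert res.b_xy == pytest.approx(0.3, abs=1e-4)
        assert res.p < 1e-4


class TestSteigerAndReverse:
    def test_locus_orientation(self, rng):
        n = 500
        g = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        exposure = g @ np.array([0.8, 0.5, 0.3]) + rng.normal(0, 1, n)
        trait = 0.1 * exposure + rng.normal(0, 1, n)
        assert steiger_locus_orientation(g, exposure, trait)
        assert not steiger_locus_orientation(g, trait, exposure)

    def test_reverse_2sls_recovers_planted_effect(self, rng):
        n = 3000
        g = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        trait = g @ np.array([0.5, 0.4]) + rng.normal(0, 1, n)
        meth = 0.4 * trait + rng.normal(0, 1, n)
        res = reverse_mr_2sls(g, trait, meth)
        assert res.coef == pytest.approx(0.4, abs=0.1)
        assert res.stage1_f > 10
        assert not res.weak_instruments
        assert res.p < 1e-4

    def test_weak_instruments_flagged(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        trait = rng.normal(0, 1, n)  # instruments irrelevant
        meth = rng.normal(0, 1, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reverse_mr_2sls(g, trait, meth)
        assert res.weak_instruments


class TestSelection:
    def test_benjamini_hochberg_hand_example(self):
        results = [
            MRResult("c1", "ivw_fe", 3, 0.3, 0.1, 0.01),
            MRResult("c2", "ivw_fe", 3, 0.2, 0.1, 0.02),
            MRResult("c3", "ivw_fe", 3, 0.0, 0.1, 0.20),
            MRResult("c4", "wald_ratio", 1, np.nan, np.nan, np.nan),
        ]
        table = select_mediators(results, fdr_q=0.05)
        qs = table.set_index("cpg")["q"]
        assert qs["c1"] == pytest.approx(0.03)   # min(0.01*3/1, q2)
        assert qs["c2"] == pytest.approx(0.03)   # 0.02*3/2
        assert qs["c3"] == pytest.approx(0.20)
        assert np.isnan(qs["c4"])
        med = table.set_index("cpg")["mediator"]
        assert med["c1"] and med["c2"]
        assert not med["c3"] and not med["c4"]


class TestFacade:
    def test_primary_dispatch_and_summary(self):
        outcome = make_summary_stats(["a", "b", "c"], [0.09, 0.15, 0.24], 0.02)
        exp1 = exposure_frame(["a"], [0.3])
        m1 = MendelianRandomization(exp1, outcome)
        r1 = m1.fit("primary")
        assert r1.method == "wald_ratio"
        assert r1.b_xy == pytest.approx(0.3)
        exp3 = exposure_frame(["a", "b", "c"], [0.3, 0.5, 0.8])
        m3 = MendelianRandomization(exp3, outcome)
        r3 = m3.fit("primary")
        assert r3.method == "ivw_fe"
        assert r3.b_xy == pytest.approx(0.3, abs=0.01)
        table = m3.fit_all()
        assert {"ivw_fe", "egger"} <= set(table["method"])
        assert "ivw" in m3.summary()
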