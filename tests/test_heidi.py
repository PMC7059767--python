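import numpy as np
import pandas as pd
import pytest

from methmediate.datatypes import LDMatrix
from methmediate.heidi import (
    HEIDIResult,
    classify_pleiotropy_vs_linkage,
    heidi_test,
    select_heidi_snps,
)


def compound_ld(snps, rho):
    m = len(snps)
    r = rho * np.ones((m, m)) + (1 - rho) * np.eye(m)
    return LDMatrix(snps, r)


class TestSelectHeidiSnps:
    def test_window_p_filter_and_cap(self):
        snps = [f"s{i}" for i in range(6)]
        r = np.eye(6)
        top = 0
        # r(top, .): s1 in window, s2 too high, s3 too low, s4/s5 in window
        for j, rij in enumerate([1.0, 0.5, 0.97, 0.1, 0.6, 0.7]):
            r[top, j] = r[j, top] = rij
        # make the matrix PSD enough for the constructor: only pairwise with top
        ld = LDMatrix(snps, (r + r.T) / 2)
        locus = pd.DataFrame({
            "snp": snps,
            "p": [1e-20, 1e-4, 1e-4, 1e-4, 1e-4, 0.5],
        })
        keep, excl = select_heidi_snps(locus, "s0", ld)
        # s1 (r2=0.25), s4 (0.36) pass; s2 r2=0.94 high, s3 r2=0.01 low,
        # s5 weak (p > 1.6e-3)
        assert set(keep) == {"s1", "s4"}
        assert excl["r2_out_of_range"] == 2
        assert excl["weak_instrument"] == 1

    def test_cap_keeps_smallest_p(self):
        snps = ["top"] + [f"s{i}" for i in range(4)]
        ld = compound_ld(snps, 0.5)
        locus = pd.DataFrame({"snp": snps, "p": [1e-20, 1e-6, 1e-5, 1e-4, 1e-3]})
        keep, excl = select_heidi_snps(locus, "top", ld, cap=2)
        assert keep == ["s0", "s1"]
        assert excl["cap"] == 2

    def test_missing_top_snp_raises(self):
        ld = compound_ld(["a", "b"], 0.3)
        with pytest.raises(ValueError):
            select_heidi_snps(pd.DataFrame({"snp": ["a", "b"], "p": [1, 1]}),
                              "zz", ld)


class TestHeidiTest:
    def table(self, b_zx, b_zy, se_zy=0.02, se_zx=0.005):
        m = len(b_zx)
        return pd.DataFrame({
            "snp": [f"s{i}" for i in range(m)],
            "b_zx": b_zx, "se_zx": se_zx,
            "b_zy": b_zy, "se_zy": se_zy,
        })

    def test_exact_proportionality_is_not_rejected(self):
        # single shared causal variant: b_zy = c * b_zx exactly at every SNP
        ld = compound_ld([f"s{i}" for i in range(5)], 0.6)
        b_zx = np.array([0.8, 0.5, 0.45, 0.52, 0.48])
        tab = self.table(b_zx, 0.3 * b_zx)
        res = heidi_test(tab, ld, top_snp="s0")
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_heidi > 0.9
        assert res.n_snp_heidi == 4

    def test_heterogeneous_ratios_are_rejected(self):
        ld = compound_ld([f"s{i}" for i in range(5)], 0.6)
        b_zx = np.array([0.8, 0.5, 0.45, 0.52, 0.48])
        b_zy = 0.3 * b_zx
        b_zy[2] += 0.5  # one SNP acts through a different variant
        res = heidi_test(self.table(b_zx, b_zy), ld, top_snp="s0")
        assert res.p_heidi < 1e-4

    def test_exact_inversion_close_to_monte_carlo(self):
        rng = np.random.default_rng(42)
        ld = compound_ld([f"s{i}" for i in range(6)], 0.5)
        b_zx = rng.uniform(0.4, 0.8, 6)
        b_zy = 0.3 * b_zx + rng.normal(0, 0.01, 6)
        tab = self.table(b_zx, b_zy)
        exact = heidi_test(tab, ld, top_snp="s0", method="imhof")
        mc = heidi_test(tab, ld, top_snp="s0", method="mc", n_mc=50000, seed=9)
        assert abs(exact.p_heidi - mc.p_heidi) < 0.01
        # the two-moment approximation lands in the same neighbourhood
        sat = heidi_test(tab, ld, top_snp="s0", method="satterthwaite")
        assert abs(sat.p_heidi - exact.p_heidi) < 0.1

    def test_single_snp_locus_is_na(self):
        ld = compound_ld(["s0"], 0.5)
        res = heidi_test(self.table([0.8], [0.24]), ld, top_snp="s0")
        assert res.is_na()
        assert res.n_snp_heidi == 0


class TestClassification:
    def test_default_alpha_is_bonferroni_over_tested(self):
        results = [
            HEIDIResult("c1", "s0", 30.0, 1e-6, 5, {}),
            HEIDIResult("c2", "s1", 2.0, 0.7, 5, {}),
            HEIDIResult("c3", None, np.nan, np.nan, 0, {}),
        ]
        out = classify_pleiotropy_vs_linkage(results)
        assert out["alpha"].iloc[0] == pytest.approx(0.05 / 2)
        verdicts = out.set_index("cpg")["verdict"]
        assert verdicts["c1"] == "linkage"
        assert verdicts["c2"].startswith("consistent")
        assert verdicts["c3"] == "NA"
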