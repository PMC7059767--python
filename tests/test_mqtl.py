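import numpy as np
import pandas as pd
import pytest

from methmediate.mqtl import (
    bonferroni_by_class,
    count_tests_by_class,
    hwe_exact_test,
    ld_matrix,
    scan_mqtl,
    snp_qc,
    MQTLScan,
)
from tests.conftest import make_counts, make_genotypes


class TestHWE:
    def test_tiny_case_by_enumeration(self):
        # allele counts A=2,a=2 over N=2 genotypes; conditional distribution
        # P(het=0) = 1/3, P(het=2) = 2/3.
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1.0 / 3.0)
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_equilibrium_configuration_has_p_one(self):
        # A=4,a=4,N=4: weights 6 (h=0), 48 (h=2), 16 (h=4); h=2 is modal.
        assert hwe_exact_test(1, 2, 1) == pytest.approx(1.0)
        # observed h=0 has probability 6/70; no other configuration is as
        # improbable, so the tail is 6/70
        assert hwe_exact_test(2, 0, 2) == pytest.approx(6.0 / 70.0)

    def test_monomorphic_is_not_rejected(self):
        assert hwe_exact_test(10, 0, 0) == pytest.approx(1.0)


class TestSNPQC:
    def test_filters_rare_and_low_call_rate(self, rng):
        n = 400
        common = rng.binomial(2, 0.3, n).astype(float)
        rare = np.zeros(n)
        rare[0] = 1.0  # MAF 1/800 < 0.01
        sparse = rng.binomial(2, 0.3, n).astype(float)
        sparse[: int(n * 0.2)] = np.nan  # call rate 0.8 < 0.95
        g = make_genotypes(np.column_stack([common, rare, sparse]))
        kept = snp_qc(g)
        assert list(kept.snps["id"]) == ["snp0"]

    def test_filters_hwe_violation(self, rng):
        n = 400
        common = rng.binomial(2, 0.3, n).astype(float)
        all_het = np.ones(n)  # gross heterozygote excess
        g = make_genotypes(np.column_stack([common, all_het]))
        kept = snp_qc(g)
        assert list(kept.snps["id"]) == ["snp0"]


class TestScan:
    def make_exact_pair(self):
        # beta value nearly linear in dosage (tiny jitter keeps se > 0)
        d = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0, 0.0, 2.0])
        jitter = np.array([1.0, -1.0, 0.0, 2.0, -2.0, 1.0, 0.0, -1.0])
        g = make_genotypes(d[:, None], positions=[1000])
        n = np.full((1, 8), 100.0)
        m = (0.3 + 0.1 * d) * 100.0 + jitter
        counts = make_counts(m[None, :], n, pos0=2000)
        return g, counts

    def test_raw_transform_matches_least_squares(self):
        g, counts = self.make_exact_pair()
        rec = scan_mqtl(g, counts, transform="raw")
        assert len(rec) == 1
        row = rec.iloc[0]
        d = g.dosages[:, 0]
        beta = counts.m[0] / counts.n[0]
        slope = np.polyfit(d, beta, 1)[0]
        assert row["b_zx"] == pytest.approx(slope, rel=1e-9)
        assert row["class"] == "cis"
        assert row["p"] < 1e-4

    def test_cis_trans_classification(self):
        d = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0], [1.0, 1.0]])
        g = make_genotypes(d, positions=[1000, 2_500_000])
        n = np.full((1, 4), 50.0)
        m = np.array([[10.0, 20.0, 30.0, 25.0]])
        counts = make_counts(m, n, pos0=1500)
        rec = scan_mqtl(g, counts)
        by_snp = rec.set_index("snp")
        assert by_snp.loc["snp0", "class"] == "cis"      # 500 bp away
        assert by_snp.loc["snp1", "class"] == "trans"    # ~2.5 Mb away
        cis_n, trans_n = count_tests_by_class(g, counts.cpgs)
        assert (cis_n, trans_n) == (1, 1)

    def test_logit_transform_matches_empirical_logit(self):
        g, counts = self.make_exact_pair()
        rec = scan_mqtl(g, counts, transform="logit")
        d = g.dosages[:, 0]
        m = counts.m[0]
        n = counts.n[0]
        y = np.log((m + 0.5) / (n - m + 0.5))
        slope = np.polyfit(d, y, 1)[0]
        assert rec.iloc[0]["b_zx"] == pytest.approx(slope, rel=1e-6)


class TestBonferroniByClass:
    def test_strict_per_class_thresholds(self):
        rec = pd.DataFrame({
            "snp": ["a", "b", "c", "d"],
            "class": ["cis", "cis", "trans", "trans"],
            "p": [0.05 / 100 - 1e-12, 0.05 / 100, 0.05 / 1000 - 1e-15, 0.05 / 100],
        })
        out = bonferroni_by_class(rec, n_cis_tests=100, n_trans_tests=1000)
        assert list(out["snp"]) == ["a", "c"]


class TestLDMatrixAndModel:
    def test_signed_correlation(self):
        d = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0], [0.0, 2.0], [2.0, 0.0]])
        g = make_genotypes(d)
        ld = ld_matrix(g)
        assert ld.r[0, 1] == pytest.approx(-1.0)
        assert ld.r2("snp0", "snp1") == pytest.approx(1.0)

    def test_model_facade(self, rng):
        n = 120
        d = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        g = make_genotypes(d)
        cov = np.full((3, n), 40.0)
        logit = -0.5 + 0.9 * d[:, 0]
        pr = 1 / (1 + np.exp(-(logit + rng.normal(0, 0.2, n))))
        m = rng.binomial(40, pr, n).astype(float)
        base = rng.binomial(40, 0.4, size=(2, n)).astype(float)
        counts = make_counts(np.vstack([m, base]), cov)
        res = MQTLScan(g, counts, add_genotype_pc1=False, qc=False).fit(alpha=0.05)
        sig = res.significant
        assert ((sig["cpg"] == "cpg0") & (sig["snp"] == "snp0")).any()
        assert res.n_cis_tests + res.n_trans_tests == 9
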