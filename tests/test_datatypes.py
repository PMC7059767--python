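import numpy as np
import pandas as pd
import pytest

from methmediate.datatypes import (
    GenotypeMatrix,
    LDMatrix,
    MethylationCounts,
    PhenotypeTable,
    SummaryStats,
)
from tests.conftest import make_counts, make_genotypes, make_phenotypes


class TestGenotypeMatrix:
    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(ValueError):
            make_genotypes([[0, 3], [1, 2]])

    def test_allows_missing_dosage(self):
        g = make_genotypes([[0, np.nan], [1, 2]])
        assert np.isnan(g.dosages[0, 1])

    def test_empirical_maf(self):
        # column 0: dosages 0,1,2 over 3 subjects -> freq 3/6 = 0.5
        # column 1: dosages 2,2,2 -> freq 1.0 -> folded to minor 0.0
        g = make_genotypes([[0, 2], [1, 2], [2, 2]])
        maf = g.empirical_maf()
        assert maf[0] == pytest.approx(0.5)
        assert maf[1] == pytest.approx(0.0)

    def test_subset_snps_preserves_requested_order(self):
        g = make_genotypes([[0, 1, 2], [2, 1, 0]])
        sub = g.subset_snps(["snp2", "snp0"])
        assert list(sub.snps["id"]) == ["snp2", "snp0"]
        np.testing.assert_array_equal(sub.dosages, [[2, 0], [0, 2]])


class TestMethylationCounts:
    def test_rejects_m_greater_than_n(self):
        with pytest.raises(ValueError):
            make_counts([[5]], [[4]])

    def test_beta_values_and_missing(self):
        c = make_counts([[3, 0]], [[10, 0]])
        beta = c.beta_values()
        assert beta[0, 0] == pytest.approx(0.3)
        assert np.isnan(beta[0, 1])  # zero coverage is missing


class TestPhenotypeTable:
    def test_requires_all_columns(self):
        with pytest.raises(ValueError):
            PhenotypeTable(pd.DataFrame({"subject": ["a"], "group": [1]}))

    def test_rejects_nonbinary_group(self):
        p = make_phenotypes([0, 1]).table.copy()
        p["group"] = [0, 2]
        with pytest.raises(ValueError):
            PhenotypeTable(p)

    def test_covariate_matrix_shape(self):
        p = make_phenotypes([0, 1, 1])
        assert p.covariate_matrix().shape == (3, 4)


class TestSummaryStats:
    def base(self):
        return pd.DataFrame({
            "id": ["s1"], "effect_allele": ["A"], "other_allele": ["G"],
            "beta_zy": [0.1], "se_zy": [0.02], "p": [1e-6],
            "eaf": [0.3], "n": [50000],
        })

    def test_rejects_nonpositive_se(self):
        t = self.base(); t["se_zy"] = 0.0
        with pytest.raises(ValueError):
            SummaryStats(t)

    def test_rejects_eaf_out_of_bounds(self):
        t = self.base(); t["eaf"] = 1.0
        with pytest.raises(ValueError):
            SummaryStats(t)

    def test_lookup(self):
        ss = SummaryStats(self.base())
        assert ss.lookup("s1")["beta_zy"] == pytest.approx(0.1)
        with pytest.raises(KeyError):
            ss.lookup("absent")


class TestLDMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_r2_and_submatrix(self):
        ld = LDMatrix(["a", "b", "c"],
                      np.array([[1.0, -0.5, 0.1],
                                [-0.5, 1.0, 0.0],
                                [0.1, 0.0, 1.0]]))
        assert ld.r2("a", "b") == pytest.approx(0.25)
        sub = ld.submatrix(["c", "a"])
        assert sub.snp_ids == ["c", "a"]
        assert sub.r[0, 1] == pytest.approx(0.1)
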