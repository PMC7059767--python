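import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmediate.ewas import EWASModel, classify_dmcs, filter_cpgs, inverse_normal_transform
from methmediate.ewas import test_dmc as fit_dmc  # aliased: not a pytest test
from tests.conftest import make_counts


class TestInverseNormalTransform:
    def test_two_values_hit_quartiles(self):
        # m=2: ranks 1,2 -> Phi^-1(0.25), Phi^-1(0.75) = -/+ 0.6744897...
        out = inverse_normal_transform(np.array([3.0, 8.0]))
        np.testing.assert_allclose(out, [-0.674489750196, 0.674489750196],
                                   atol=1e-9)

    def test_ties_share_average_rank(self):
        out = inverse_normal_transform(np.array([1.0, 1.0, 2.0]))
        # tied ranks (1.5, 1.5, 3) -> Phi^-1(1/3) twice, Phi^-1(2.5/3)
        assert out[0] == pytest.approx(out[1])
        assert out[0] == pytest.approx(stats.norm.ppf(1.0 / 3.0))
        assert out[2] == pytest.approx(stats.norm.ppf(2.5 / 3.0))

    def test_missing_preserved_and_minimum_size(self):
        out = inverse_normal_transform(np.array([1.0, np.nan, 2.0]))
        assert np.isnan(out[1]) and np.isfinite(out[0])
        with pytest.raises(ValueError):
            inverse_normal_transform(np.array([1.0, np.nan]))


class TestFilterCpgs:
    def test_coverage_filter(self):
        # cpg0 covered everywhere; cpg1 uncovered in group 0
        n = np.array([[10, 10, 10, 10],
                      [0, 0, 10, 10]], dtype=float)
        m = np.zeros_like(n)
        counts = make_counts(m, n)
        kept, n_ret, n_tot = filter_cpgs(counts, np.array([0, 0, 1, 1]),
                                         min_coverage=3, min_subjects_per_group=2)
        assert (n_ret, n_tot) == (1, 2)
        assert list(kept.cpgs["id"]) == ["cpg0"]

    def test_requires_both_groups(self):
        counts = make_counts([[1, 1]], [[5, 5]])
        with pytest.raises(ValueError):
            filter_cpgs(counts, np.array([1, 1]))


class TestDMCGLM:
    def test_matches_two_by_two_log_odds(self):
        # constant counts per group: the binomial GLM equals the aggregated
        # 2x2 table. group0 m=3/n=9 (odds 0.5), group1 m=6/n=9 (odds 2):
        # logOR = log 4; Wald se = sqrt(sum of 1/cell) on aggregated counts.
        per_group = 40
        m = np.array([3.0] * per_group + [6.0] * per_group)
        n = np.full(2 * per_group, 9.0)
        grp = np.array([0] * per_group + [1] * per_group)
        res = fit_dmc(m, n, grp, cpg="cpgX")
        m0, u0 = 3 * per_group, 6 * per_group
        m1, u1 = 6 * per_group, 3 * per_group
        log_or = np.log((m1 / u1) / (m0 / u0))
        se = np.sqrt(1 / m0 + 1 / u0 + 1 / m1 + 1 / u1)
        p = 2 * stats.norm.sf(abs(log_or / se))
        assert res.beta1 == pytest.approx(log_or, abs=1e-6)
        assert res.se_beta1 == pytest.approx(se, rel=1e-4)
        assert res.p == pytest.approx(p, rel=1e-3)
        assert res.converged

    def test_meth_diff_is_percent(self):
        m = np.array([3.0, 3.0, 6.0, 6.0])
        n = np.full(4, 10.0)
        res = fit_dmc(m, n, np.array([0, 0, 1, 1]))
        assert res.meth_diff == pytest.approx(30.0)

    def test_zero_coverage_subjects_dropped(self):
        m = np.array([3.0, 0.0, 6.0, 6.0])
        n = np.array([10.0, 0.0, 10.0, 10.0])
        res = fit_dmc(m, n, np.array([0, 0, 1, 1]))
        assert np.isfinite(res.beta1)


class TestClassifyDmcs:
    def table(self, p, diff):
        return pd.DataFrame({"cpg": [f"c{i}" for i in range(len(p))],
                             "p": p, "meth_diff": diff})

    def test_bonferroni_is_strict(self):
        t = self.table([0.05 / 10, 0.05 / 10 - 1e-12], [20.0, 20.0])
        out = classify_dmcs(t, alpha=0.05, diff_threshold=0.05, n_tested=10)
        assert list(out["cpg"]) == ["c1"]

    def test_difference_rule_strict_at_5_inclusive_at_10(self):
        t = self.table([1e-9, 1e-9], [5.0, 10.0])
        at5 = classify_dmcs(t, diff_threshold=0.05, n_tested=2)
        assert list(at5["cpg"]) == ["c1"]  # exactly 5% excluded
        at10 = classify_dmcs(t, diff_threshold=0.10, n_tested=2)
        assert list(at10["cpg"]) == ["c1"]  # exactly 10% included


class TestEWASModel:
    def test_fit_returns_results_with_summary(self, rng):
        n_cpg, n_sub = 6, 80
        grp = np.repeat([0, 1], n_sub // 2)
        n = rng.poisson(30, size=(n_cpg, n_sub)).astype(float) + 5
        base = rng.uniform(0.3, 0.6, size=n_cpg)
        prob = np.tile(base[:, None], (1, n_sub))
        prob[0, grp == 1] += 0.25  # one genuinely differential CpG
        m = rng.binomial(n.astype(int), prob).astype(float)
        counts = make_counts(m, n)
        model = EWASModel(counts, grp, add_meth_pc1=False)
        res = model.fit()
        assert set(["cpg", "p", "meth_diff"]) <= set(res.table.columns)
        assert res.n_tested == n_cpg
        dmcs = res.dmcs()
        assert "cpg0" in list(dmcs["cpg"])
        assert "CpGs tested" in res.summary()
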