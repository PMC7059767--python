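import numpy as np
import pytest
from scipy.stats import multivariate_normal

from methmediate.finemap import (
    DEFAULT_RIDGE,
    FineMap,
    LocusData,
    config_likelihood,
    config_prior,
    em_fit_annotations,
    enumerate_posteriors,
)


def compound_locus(cpg="l0", m=5, rho=0.5, causal=0, z_causal=5.0,
                   annotations=None, seed=0):
    rng = np.random.default_rng(seed)
    sigma = rho * np.ones((m, m)) + (1 - rho) * np.eye(m)
    L = np.linalg.cholesky(sigma + 1e-9 * np.eye(m))
    z = z_causal * sigma[causal] + L @ rng.standard_normal(m)
    return LocusData(cpg, [f"{cpg}_s{j}" for j in range(m)], z, sigma,
                     annotations)


class TestLikelihoodAndPrior:
    def test_config_likelihood_matches_direct_mvn(self):
        locus = compound_locus(m=4, seed=3)
        S = locus.sigma + DEFAULT_RIDGE * np.eye(4)
        w2 = 25.0
        for c in [(), (1,), (0, 2)]:
            if c:
                idx = list(c)
                cov = S + w2 * S[:, idx] @ S[idx, :]
            else:
                cov = S
            direct = multivariate_normal.logpdf(locus.z, mean=np.zeros(4),
                                                cov=cov)
            assert config_likelihood(locus, c, w2=w2) == pytest.approx(
                direct, abs=1e-9)

    def test_config_prior_bernoulli_oracle(self):
        ann = np.zeros((3, 0))
        a0 = np.log(0.2 / 0.8)
        a = np.zeros(0)
        assert config_prior((), ann, a0, a) == pytest.approx(3 * np.log(0.8))
        assert config_prior((0,), ann, a0, a) == pytest.approx(
            np.log(0.2) + 2 * np.log(0.8))

    def test_annotation_shifts_prior(self):
        ann = np.array([[1], [0]])
        a0, a = np.log(0.1 / 0.9), np.array([np.log(5.0)])
        # annotated SNP has prior odds 5x the baseline
        p_ann = np.exp(config_prior((0,), ann, a0, a))
        p_base = np.exp(config_prior((1,), ann, a0, a))
        odds_ratio = (p_ann / (1)) / (p_base / 1)
        # ratio of pi/(1-pi) terms equals the annotation odds
        pi_ann = 1 / (1 + np.exp(-(a0 + a[0])))
        pi_base = 1 / (1 + np.exp(-a0))
        expected = (pi_ann * (1 - pi_base)) / (pi_base * (1 - pi_ann))
        assert (pi_ann / (1 - pi_ann)) / (pi_base / (1 - pi_base)) == \
            pytest.approx(5.0)
        assert p_ann / p_base == pytest.approx(expected)


class TestEnumeration:
    def test_posteriors_normalize_and_pip_consistent(self):
        locus = compound_locus(m=5, seed=1)
        post = enumerate_posteriors(locus)
        assert np.exp(post.log_post).sum() == pytest.approx(1.0)
        # PIP_j must equal the summed posterior of configurations containing j
        for j in range(5):
            mass = sum(np.exp(lp) for c, lp in zip(post.configs, post.log_post)
                       if j in c)
            assert post.pip[j] == pytest.approx(mass, abs=1e-12)

    def test_strong_signal_snp_gets_top_pip(self):
        locus = compound_locus(m=6, causal=2, z_causal=7.0, seed=5)
        post = enumerate_posteriors(locus)
        assert int(np.argmax(post.pip)) == 2
        assert post.top_causal == "l0_s2"

    def test_snp_cap_enforced(self):
        locus = compound_locus(m=5)
        with pytest.raises(ValueError):
            enumerate_posteriors(locus, max_snps=4)


class TestEM:
    def test_marginal_history_is_nondecreasing(self):
        rng = np.random.default_rng(8)
        loci = []
        for i in range(12):
            m = 8
            causal = int(rng.integers(m))
            ann = rng.binomial(1, np.where(np.arange(m) == causal, 0.6, 0.1))
            loci.append(compound_locus(f"l{i}", m=m, causal=causal,
                                       z_causal=6.0,
                                       annotations=ann[:, None], seed=100 + i))
        a0, a, hist = em_fit_annotations(loci)
        assert len(a) == 1
        diffs = np.diff(hist)
        assert (diffs >= -1e-8).all()
        assert np.exp(a[0]) > 1.0  # enrichment direction recovered

    def test_facade_reports_causal_mqtls(self):
        loci = [compound_locus(f"l{i}", m=6, causal=1, z_causal=6.0,
                               seed=200 + i) for i in range(3)]
        res = FineMap(loci).fit()
        table = res.causal_mqtls()
        assert list(table["cpg"]) == ["l0", "l1", "l2"]
        assert (table["pip"] > 0).all()
        assert "l0" in res.summary()
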