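import numpy as np
import pytest

from methmediate.simulate import (
    SimulationConfig,
    latent_rho_for_dosage_corr,
    simulate_annotations,
    simulate_dataset,
    simulate_genotypes,
)


def small_config(**kw):
    base = dict(n_subjects=80, n_outcome_gwas=4000, n_snps=12, n_cpgs=10,
                n_instruments=2, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_blocks_recycle_to_cover_panel(self):
        cfg = SimulationConfig(n_snps=30, ld_block_spec=[(6, 0.8)])
        assert cfg.blocks() == [(6, 0.8)] * 5
        cfg = SimulationConfig(n_snps=8, ld_block_spec=[(6, 0.8)])
        assert cfg.blocks() == [(6, 0.8), (2, 0.8)]

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario="nope")
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(group_z_threshold=0.0)


class TestGenotypes:
    def test_block_ld_calibration(self):
        # large sample: dosage correlation of adjacent block SNPs matches the
        # value the latent-threshold model predicts for latent rho = 0.8
        from methmediate.simulate import _dosage_corr_from_latent
        cfg = SimulationConfig(n_snps=6, n_subjects=6000, seed=3)
        g = simulate_genotypes(cfg, n=6000, rng=np.random.default_rng(3))
        d = g.dosages
        r = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
        expected = _dosage_corr_from_latent(
            0.8, float(g.snps["maf"].iloc[0]), float(g.snps["maf"].iloc[1]))
        assert abs(r - expected) < 0.06
        assert r > 0.2

    def test_dosages_are_biallelic_counts(self):
        ds = simulate_dataset(small_config())
        vals = ds.genotypes.dosages
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}


class TestDataset:
    def test_determinism_and_seed_sensitivity(self):
        a = simulate_dataset(small_config())
        b = simulate_dataset(small_config())
        c = simulate_dataset(small_config(seed=12))
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_array_equal(a.methylation.m, b.methylation.m)
        np.testing.assert_allclose(a.gwas.table["beta_zy"], b.gwas.table["beta_zy"])
        assert not np.array_equal(a.genotypes.dosages, c.genotypes.dosages)

    def test_shapes_and_truth(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        assert ds.genotypes.dosages.shape == (80, 12)
        assert ds.methylation.m.shape == (10, 80)
        assert len(ds.phenotypes.table) == 80
        assert len(ds.gwas.table) == 12
        assert (ds.gwas.table["n"] == 4000).all()
        truth = ds.truth
        assert truth["causal_cpgs"] == ["cpg00000"]
        assert len(truth["meth_causal_snps"]) == cfg.n_instruments

    def test_extreme_group_recruitment(self):
        cfg = small_config(group_z_threshold=0.8)
        ds = simulate_dataset(cfg)
        y = ds.phenotypes.table["y_continuous"].to_numpy()
        grp = ds.phenotypes.group
        assert set(grp) == {0, 1}
        assert (np.abs(y) >= 0.8).all()
        assert (y[grp == 1] > 0).all() and (y[grp == 0] < 0).all()

    def test_null_scenario_has_no_causal_structure(self):
        ds = simulate_dataset(small_config(scenario="null"))
        assert ds.truth["causal_cpgs"] == []
        assert ds.truth["meth_causal_snps"] == []

    def test_reverse_scenario_plants_trait_snps(self):
        ds = simulate_dataset(small_config(scenario="reverse"))
        assert len(ds.truth["trait_snps"]) > 0
        assert ds.truth["meth_causal_snps"] == []


class TestHelpers:
    def test_latent_rho_monotone_and_bounded(self):
        lo = latent_rho_for_dosage_corr(0.3, 0.2, 0.2)
        hi = latent_rho_for_dosage_corr(0.7, 0.2, 0.2)
        assert 0 < lo < hi < 1

    def test_annotations_shape_and_enrichment(self, rng):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        ann = simulate_annotations(ds.genotypes, ds.truth["meth_causal_snps"],
                                   enrichment_odds=5.0, n_tracks=2, seed=5)
        assert ann.shape == (12, 2)
        assert set(np.unique(ann)) <= {0, 1}
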