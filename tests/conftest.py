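"""Shared builders for small, fully hand-specified test fixtures."""

import numpy as np
import pandas as pd
import pytest

from methmediate.datatypes import (
    GenotypeMatrix,
    MethylationCounts,
    PhenotypeTable,
    SummaryStats,
)


def make_genotypes(dosages, chrom="chr1", pos0=1000, spacing=100,
                   chroms=None, positions=None):
    """GenotypeMatrix from a plain dosage array with generated metadata."""
    d = np.asarray(dosages, dtype=float)
    m = d.shape[1]
    with np.errstate(invalid="ignore"):
        maf = np.clip(np.nanmean(d, axis=0) / 2.0, 0.01, 0.5)
    snps = pd.DataFrame({
        "id": [f"snp{j}" for j in range(m)],
        "chrom": chroms if chroms is not None else [chrom] * m,
        "pos": positions if positions is not None else
               [pos0 + spacing * j for j in range(m)],
        "effect_allele": ["A"] * m,
        "other_allele": ["G"] * m,
        "maf": maf,
    })
    return GenotypeMatrix(d, snps)


def make_counts(m, n, chrom="chr1", pos0=500, spacing=50):
    """MethylationCounts from plain count arrays with generated metadata."""
    m = np.asarray(m, dtype=float)
    cpgs = pd.DataFrame({
        "id": [f"cpg{k}" for k in range(m.shape[0])],
        "chrom": [chrom] * m.shape[0],
        "pos": [pos0 + spacing * k for k in range(m.shape[0])],
        "strand": ["+"] * m.shape[0],
    })
    return MethylationCounts(cpgs, m, np.asarray(n, dtype=float))


def make_summary_stats(ids, beta, se, eaf=0.3, n=50000,
                       effect="A", other="G"):
    """SummaryStats with uniform alleles unless overridden per SNP."""
    k = len(ids)
    beta = np.asarray(beta, dtype=float)
    se = np.broadcast_to(np.asarray(se, dtype=float), (k,)).copy()
    from scipy import stats
    p = 2 * stats.norm.sf(np.abs(beta / se))
    table = pd.DataFrame({
        "id": ids,
        "effect_allele": effect if isinstance(effect, list) else [effect] * k,
        "other_allele": other if isinstance(other, list) else [other] * k,
        "beta_zy": beta,
        "se_zy": se,
        "p": np.clip(p, 1e-300, 1.0),
        "eaf": np.broadcast_to(np.asarray(eaf, dtype=float), (k,)).copy(),
        "n": [n] * k,
    })
    return SummaryStats(table)


def make_phenotypes(group, y=None):
    g = np.asarray(group, dtype=int)
    n = len(g)
    table = pd.DataFrame({
        "subject": [f"S{i:04d}" for i in range(n)],
        "y_continuous": y if y is not None else np.where(g == 1, 1.2, -1.2),
        "group": g,
        "age": np.full(n, 30.0),
        "bmi": np.full(n, 25.0),
        "smoking": np.zeros(n),
        "drinking": np.zeros(n),
    })
    return PhenotypeTable(table)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
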