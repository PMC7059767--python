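"""Core in-memory containers shared across the pipeline stages.

Conventions
-----------
* Genomic positions are 1-based base pairs everywhere in memory (VCF and
  Bismark-coverage convention); BED interchange converts at the boundary.
* Genotypes are additive allele dosages in {0, 1, 2}; missing values are NaN.
* Methylation is carried as paired (methylated, total) read counts; the
  derived beta-value m/n lives on the 0-1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MethylationCounts",
    "PhenotypeTable",
    "SummaryStats",
    "LDMatrix",
]


@dataclass
class GenotypeMatrix:
    """Subject-by-SNP dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_subjects, n_snps)
        Allele counts of the effect allele in {0, 1, 2}; NaN marks missing.
    snps : pandas.DataFrame
        One row per SNP with columns ``id``, ``chrom``, ``pos`` (1-based),
        ``effect_allele``, ``other_allele`` and ``maf``.
    subjects : list of str, optional
        Subject identifiers; defaults to ``S000..``.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    subjects: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D subject x SNP matrix")
        if len(self.snps) != self.dosages.shape[1]:
            raise ValueError(
                f"snps table has {len(self.snps)} rows but dosage matrix has "
                f"{self.dosages.shape[1]} columns"
            )
        if not self.subjects:
            self.subjects = [f"S{i:04d}" for i in range(self.dosages.shape[0])]
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0, 1, 2} or missing")
        if self.snps["id"].duplicated().any():
            dup = self.snps.loc[self.snps["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup}")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive (1-based)")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snps["id"].to_numpy() == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown SNP id: {snp_id}")
        return int(idx[0])

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        cols = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            self.dosages[:, cols],
            self.snps.iloc[cols].reset_index(drop=True),
            list(self.subjects),
        )

    def subset_subjects(self, rows) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            self.dosages[rows],
            self.snps.copy(),
            [self.subjects[i] for i in rows],
        )

    def empirical_maf(self) -> np.ndarray:
        """Minor-allele frequency of the observed dosages, per SNP."""
        p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class MethylationCounts:
    """Per-CpG, per-subject methylated/total read counts.

    ``m`` and ``n`` are CpG-by-subject integer arrays; entries with ``n == 0``
    are treated as missing.
    """

    cpgs: pd.DataFrame  # columns: id, chrom, pos, strand
    m: np.ndarray
    n: np.ndarray
    subjects: list = field(default_factory=list)

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.m.shape != self.n.shape:
            raise ValueError("m and n must share a shape")
        if len(self.cpgs) != self.m.shape[0]:
            raise ValueError("cpgs table and count matrices disagree on CpG count")
        if not self.subjects:
            self.subjects = [f"S{i:04d}" for i in range(self.m.shape[1])]
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.m < 0) | (self.m > self.n))
        if bad:
            raise ValueError("methylated counts must satisfy 0 <= m <= n")
        self.cpgs = self.cpgs.reset_index(drop=True)

    @property
    def n_cpgs(self) -> int:
        return self.m.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.m.shape[1]

    def beta_values(self) -> np.ndarray:
        """m/n on the 0-1 scale; NaN where coverage is zero or missing."""
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(self.n > 0, self.m / self.n, np.nan)
        return b

    def subset_cpgs(self, rows) -> "MethylationCounts":
        rows = np.asarray(rows)
        return MethylationCounts(
            self.cpgs.iloc[rows].reset_index(drop=True),
            self.m[rows],
            self.n[rows],
            list(self.subjects),
        )

    def subset_subjects(self, cols) -> "MethylationCounts":
        cols = np.asarray(cols)
        return MethylationCounts(
            self.cpgs.copy(),
            self.m[:, cols],
            self.n[:, cols],
            [self.subjects[i] for i in cols],
        )


@dataclass
class PhenotypeTable:
    """Per-subject phenotype and covariates for the methylation cohort.

    ``group`` is the extreme-phenotype label (1 = high, 0 = low); retained
    subjects satisfy |y_continuous| >= the recruitment Z threshold.
    """

    table: pd.DataFrame  # columns: subject, y_continuous, group, age, bmi, smoking, drinking

    REQUIRED = ("subject", "y_continuous", "group", "age", "bmi", "smoking", "drinking")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if not set(self.table["group"].unique()) <= {0, 1}:
            raise ValueError("group must be binary 0/1")
        self.table = self.table.reset_index(drop=True)

    @property
    def subjects(self) -> list:
        return list(self.table["subject"])

    @property
    def group(self) -> np.ndarray:
        return self.table["group"].to_numpy(dtype=int)

    def covariate_matrix(self, names=("age", "bmi", "smoking", "drinking")) -> np.ndarray:
        return self.table[list(names)].to_numpy(dtype=float)


@dataclass
class SummaryStats:
    """Outcome-GWAS marginal effect records (the two-sample side).

    One row per SNP with columns ``id``, ``effect_allele``, ``other_allele``,
    ``beta_zy`` (phenotype SD per effect allele), ``se_zy``, ``p``, ``eaf``
    and ``n``.
    """

    table: pd.DataFrame

    REQUIRED = ("id", "effect_allele", "other_allele", "beta_zy", "se_zy", "p", "eaf", "n")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        t = self.table
        if (t["se_zy"] <= 0).any():
            raise ValueError("se_zy must be strictly positive")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("p must lie in (0, 1]")
        if ((t["eaf"] <= 0) | (t["eaf"] >= 1)).any():
            raise ValueError("eaf must lie in (0, 1)")
        self.table = t.reset_index(drop=True)

    def lookup(self, snp_id: str) -> pd.Series:
        hit = self.table[self.table["id"] == snp_id]
        if hit.empty:
            raise KeyError(f"SNP {snp_id} absent from summary statistics")
        return hit.iloc[0]


@dataclass
class LDMatrix:
    """Signed Pearson dosage-correlation matrix over an ordered SNP set."""

    snp_ids: list
    r: np.ndarray
    source_n: int = 0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("r must be square and match snp_ids")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-8:
            raise ValueError("|r| must not exceed 1")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def submatrix(self, snp_ids) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)], self.source_n)

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)
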