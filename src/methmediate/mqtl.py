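"""SNP QC, genotype PCs, cis/trans mQTL scanning, and LD matrices.

The mQTL scan regresses (by default inverse-normal transformed) methylation
levels of each differentially methylated CpG on additive SNP dosage with
covariates, pairing each CpG with every SNP on the same chromosome. A pair is
cis when SNP and CpG lie within 1 Mb of each other and trans otherwise, and
Bonferroni correction is applied separately within each class using the full
enumerated pair counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from methmediate.datatypes import GenotypeMatrix, LDMatrix, MethylationCounts
from methmediate.ewas import inverse_normal_transform

__all__ = [
    "hwe_exact_test",
    "snp_qc",
    "genotype_pcs",
    "scan_mqtl",
    "bonferroni_by_class",
    "ld_matrix",
    "MQTLScan",
]

CIS_WINDOW = 1_000_000  # bp; cis iff same chromosome and distance < 1 Mb


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Enumerates the distribution of the heterozygote count conditional on the
    allele counts and sums the probabilities of all configurations no more
    probable than the observed one (mid-p off).
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n == 0:
        return 1.0
    # possible het counts share parity with the rare-allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log-probabilities P(het | allele counts)
    from scipy.special import gammaln

    def logp(h):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        return (
            h * np.log(2)
            - gammaln(rare_hom + 1)
            - gammaln(h + 1)
            - gammaln(common_hom + 1)
        )

    logs = np.array([logp(h) for h in het_values])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(het_values == n_het)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def snp_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
) -> GenotypeMatrix:
    """Filter SNPs on empirical MAF, call rate and exact HWE p-value."""
    d = g.dosages
    n = d.shape[0]
    called = np.isfinite(d)
    call_rate = called.mean(axis=0)
    keep = call_rate > call_rate_min
    maf = np.full(d.shape[1], 0.0)
    hwe_p = np.ones(d.shape[1])
    for j in range(d.shape[1]):
        col = d[called[:, j], j]
        if col.size == 0:
            keep[j] = False
            continue
        p = col.mean() / 2.0
        maf[j] = min(p, 1 - p)
        counts = [(col == k).sum() for k in (0, 1, 2)]
        hwe_p[j] = hwe_exact_test(*counts)
    keep &= (maf > maf_min) & (hwe_p > hwe_p_min)
    return g.subset_snps(g.snps["id"].iloc[np.flatnonzero(keep)])


def genotype_pcs(g: GenotypeMatrix, k: int = 1):
    """Principal components of the standardized dosage matrix (ancestry axes)."""
    d = g.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    X = (d - d.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    return u[:, :k] * s[:k], var[:k] / var.sum()


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


@dataclass
class MQTLRecord:
    snp: str
    cpg: str
    b_zx: float
    se_zx: float
    p: float
    klass: str  # "cis" or "trans"
    distance: int


def _pair_class(snp_chrom, snp_pos, cpg_chrom, cpg_pos):
    if snp_chrom != cpg_chrom:
        return None, None
    dist = abs(int(snp_pos) - int(cpg_pos))
    return ("cis" if dist < CIS_WINDOW else "trans"), dist


def scan_mqtl(
    g: GenotypeMatrix,
    meth: MethylationCounts,
    cpg_ids=None,
    covariates: np.ndarray | None = None,
    transform: str = "int",
) -> pd.DataFrame:
    """Additive-model scan of every same-chromosome SNP-CpG pair.

    ``transform`` selects the methylation response: ``"int"`` (rank-based
    inverse normal, the default), ``"raw"`` beta-values, or ``"logit"``
    (empirical logit log((m+0.5)/(n-m+0.5)), on the generative scale of the
    simulator). Missing dosages are handled pairwise-complete.

    Returns a DataFrame with columns snp, cpg, chrom, snp_pos, cpg_pos,
    class, distance, b_zx, se_zx, p.
    """
    if meth.n_subjects != g.n_subjects:
        raise ValueError("genotype and methylation subjects are not aligned")
    if cpg_ids is None:
        cpg_ids = list(meth.cpgs["id"])
    cpg_idx = {c: i for i, c in enumerate(meth.cpgs["id"])}
    n = g.n_subjects
    if covariates is None:
        C = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        keep = covariates.std(axis=0) > 0  # drop constant columns
        C = np.column_stack([np.ones(n), covariates[:, keep]])
    k_cov = C.shape[1]

    beta_all = meth.beta_values()
    rows = []
    snp_chrom = g.snps["chrom"].to_numpy()
    snp_pos = g.snps["pos"].to_numpy()
    for cpg in cpg_ids:
        i = cpg_idx[cpg]
        c_chrom = meth.cpgs["chrom"].iloc[i]
        c_pos = int(meth.cpgs["pos"].iloc[i])
        if transform == "int":
            y = inverse_normal_transform(beta_all[i])
        elif transform == "raw":
            y = beta_all[i].copy()
        elif transform == "logit":
            with np.errstate(invalid="ignore", divide="ignore"):
                y = np.where(
                    meth.n[i] > 0,
                    np.log((meth.m[i] + 0.5) / (meth.n[i] - meth.m[i] + 0.5)),
                    np.nan,
                )
        else:
            raise ValueError(f"unknown transform {transform!r}")
        same = np.flatnonzero(snp_chrom == c_chrom)
        if same.size == 0:
            continue
        y_obs = np.isfinite(y)
        for j in same:
            gcol = g.dosages[:, j]
            ok = y_obs & np.isfinite(gcol)
            n_ok = int(ok.sum())
            if n_ok <= k_cov + 1:
                continue
            gv = gcol[ok]
            if gv.min() == gv.max():
                warnings.warn(
                    f"SNP {g.snps['id'].iloc[j]} monomorphic after missingness at "
                    f"{cpg}; pair skipped",
                    stacklevel=2,
                )
                continue
            Ck = C[ok]
            yr = _residualize(y[ok], Ck)
            gr = _residualize(gv, Ck)
            sxx = gr @ gr
            if sxx <= 0:
                continue
            b = (gr @ yr) / sxx
            rss = yr @ yr - b * (gr @ yr)
            df = n_ok - k_cov - 1
            se = np.sqrt(max(rss, 0.0) / df / sxx)
            if se == 0:
                continue
            p = 2 * stats.t.sf(abs(b / se), df=df)
            klass, dist = _pair_class(snp_chrom[j], snp_pos[j], c_chrom, c_pos)
            rows.append(
                (g.snps["id"].iloc[j], cpg, c_chrom, int(snp_pos[j]), c_pos,
                 klass, dist, b, se, max(p, np.finfo(float).tiny))
            )
    return pd.DataFrame(
        rows,
        columns=["snp", "cpg", "chrom", "snp_pos", "cpg_pos", "class",
                 "distance", "b_zx", "se_zx", "p"],
    )


def count_tests_by_class(g: GenotypeMatrix, cpgs: pd.DataFrame):
    """Full enumeration of same-chromosome pairs, split into cis/trans counts."""
    n_cis = n_trans = 0
    snp_chrom = g.snps["chrom"].to_numpy()
    snp_pos = g.snps["pos"].to_numpy()
    for _, row in cpgs.iterrows():
        same = snp_chrom == row["chrom"]
        if not same.any():
            continue
        dist = np.abs(snp_pos[same] - int(row["pos"]))
        n_cis += int((dist < CIS_WINDOW).sum())
        n_trans += int((dist >= CIS_WINDOW).sum())
    return n_cis, n_trans


def bonferroni_by_class(
    records: pd.DataFrame,
    n_cis_tests: int,
    n_trans_tests: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep records significant under the per-class Bonferroni threshold.

    cis records must satisfy p < alpha/n_cis_tests and trans records
    p < alpha/n_trans_tests (strict inequalities).
    """
    if (n_cis_tests == 0 and (records["class"] == "cis").any()) or (
        n_trans_tests == 0 and (records["class"] == "trans").any()
    ):
        raise ValueError("test counts must be positive for observed classes")
    out = records.copy()
    thr = np.where(
        out["class"] == "cis",
        alpha / n_cis_tests if n_cis_tests else np.nan,
        alpha / n_trans_tests if n_trans_tests else np.nan,
    )
    sig = out["p"].to_numpy() < thr
    out["p_bonf"] = np.minimum(
        1.0,
        out["p"] * np.where(out["class"] == "cis", n_cis_tests, n_trans_tests),
    )
    return out[sig]


def ld_matrix(g: GenotypeMatrix, snp_ids=None) -> LDMatrix:
    """Signed Pearson dosage correlations on pairwise-complete observations."""
    if snp_ids is None:
        snp_ids = list(g.snps["id"])
    if len(snp_ids) == 0:
        raise ValueError("need at least one SNP")
    sub = g.subset_snps(snp_ids)
    d = sub.dosages
    for j, s in enumerate(snp_ids):
        col = d[np.isfinite(d[:, j]), j]
        if col.size < 2:
            raise ValueError(f"SNP {s}: fewer than 2 complete observations")
        if col.min() == col.max():
            raise ValueError(f"SNP {s} is monomorphic; correlation undefined")
    r = pd.DataFrame(d).corr(min_periods=2).to_numpy()
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    eigmin = float(np.linalg.eigvalsh(r).min())
    if eigmin < -1e-6:
        warnings.warn(
            f"pairwise-complete LD matrix is indefinite (min eig {eigmin:.2e}); "
            "downstream ridge regularization applies",
            stacklevel=2,
        )
    return LDMatrix(list(snp_ids), r, source_n=g.n_subjects)


class MQTLScan:
    """Model object bundling QC, the scan, and per-class Bonferroni selection.

    Parameters
    ----------
    g : GenotypeMatrix (hard-called dosages)
    meth : MethylationCounts
    cpg_ids : CpGs (typically the DMCs) to scan; default all.
    covariates : subject-level covariates; the first genotype PC is appended
        automatically unless ``add_genotype_pc1=False``.
    """

    def __init__(self, g, meth, cpg_ids=None, covariates=None,
                 add_genotype_pc1: bool = True, transform: str = "int",
                 qc: bool = True, maf_min: float = 0.01,
                 call_rate_min: float = 0.95, hwe_p_min: float = 1e-6):
        self.g = snp_qc(g, maf_min, call_rate_min, hwe_p_min) if qc else g
        self.meth = meth
        self.cpg_ids = cpg_ids
        self.transform = transform
        cov = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
        if add_genotype_pc1 and self.g.n_snps >= 2:
            pc1, _ = genotype_pcs(self.g, 1)
            cov = pc1 if cov is None else np.column_stack([cov, pc1])
        self.covariates = cov

    def fit(self, alpha: float = 0.05) -> "MQTLResults":
        records = scan_mqtl(self.g, self.meth, self.cpg_ids,
                            self.covariates, self.transform)
        cpg_ids = self.cpg_ids if self.cpg_ids is not None else list(self.meth.cpgs["id"])
        cpgs = self.meth.cpgs[self.meth.cpgs["id"].isin(cpg_ids)]
        n_cis, n_trans = count_tests_by_class(self.g, cpgs)
        sig = bonferroni_by_class(records, max(n_cis, 1), max(n_trans, 1), alpha) \
            if len(records) else records.assign(p_bonf=[])
        return MQTLResults(records, sig, n_cis, n_trans, self)


class MQTLResults:
    def __init__(self, records, significant, n_cis_tests, n_trans_tests, model):
        self.records = records
        self.significant = significant
        self.n_cis_tests = n_cis_tests
        self.n_trans_tests = n_trans_tests
        self.model = model

    def summary(self) -> str:
        n_cis_sig = int((self.significant["class"] == "cis").sum()) if len(self.significant) else 0
        n_trans_sig = len(self.significant) - n_cis_sig
        lines = [
            "cis/trans mQTL scan (additive linear model)",
            f"  enumerated cis tests:   {self.n_cis_tests}",
            f"  enumerated trans tests: {self.n_trans_tests}",
            f"  significant cis mQTLs:  {n_cis_sig}",
            f"  significant trans mQTLs:{n_trans_sig}",
        ]
        return "\n".join(lines)
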