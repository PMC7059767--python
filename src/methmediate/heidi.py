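"""HEIDI: heterogeneity in dependent instruments.

Under a single shared causal variant (vertical pleiotropy through
methylation), the ratio estimate b_xy = b_zy / b_zx is the same no matter
which SNP in LD with the causal variant computes it. Under linkage -- two
distinct causal variants in LD, one driving methylation and one the trait --
the ratios disagree. HEIDI tests the null of homogeneity by contrasting the
ratio at every locus SNP against the ratio at the top mQTL SNP:

    d_i = b_xy_i - b_xy_top,   T = sum_i (d_i / sd(d_i))^2.

The covariance of d is assembled by the first-order delta method treating the
(strongly significant) exposure effects b_zx as fixed, with the GWAS-side
correlation induced by LD:

    cov(b_xy_i, b_xy_j) = r_ij * se_zy_i * se_zy_j / (b_zx_i * b_zx_j).

T follows a weighted sum of one-degree chi-squares whose weights are the
eigenvalues of the correlation matrix of d; the default p-value inverts that
distribution exactly by Imhof's characteristic-function integral. The
Satterthwaite scaled-chi-square (two-moment) approximation and a
multivariate-normal Monte-Carlo computation are available as cross-checks;
the two-moment approximation can drift a few percent from the exact tail on
small or strongly correlated SNP sets.

Locus SNPs enter only if in moderate LD with the top SNP
(0.05 < r^2 < 0.9) and strongly associated with methylation
(mQTL p <= 1.6e-3, guarding against weak-instrument bias); at most ``cap``
SNPs (smallest mQTL p) are used. A small HEIDI p rejects the shared-variant
null in favour of linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, stats

from methmediate.datatypes import LDMatrix, SummaryStats
from methmediate.mr import harmonize

__all__ = [
    "select_heidi_snps",
    "heidi_test",
    "classify_pleiotropy_vs_linkage",
    "HeidiTest",
    "HEIDIResult",
]


@dataclass
class HEIDIResult:
    cpg: str
    top_snp: str
    t_stat: float
    p_heidi: float
    n_snp_heidi: int
    excluded: dict = field(default_factory=dict)

    def is_na(self) -> bool:
        return self.n_snp_heidi < 1 or not np.isfinite(self.p_heidi)


def select_heidi_snps(
    locus: pd.DataFrame,
    top_snp: str,
    ld: LDMatrix,
    r2_low: float = 0.05,
    r2_high: float = 0.9,
    p_max: float = 1.6e-3,
    cap: int = 20,
):
    """Choose the locus SNPs contrasted against the top mQTL SNP.

    Keeps SNPs with r2_low < r^2(snp, top) < r2_high and mQTL p <= p_max;
    if more than ``cap`` qualify, the ``cap`` with smallest mQTL p are used.
    Returns (snp id list, exclusion counts by reason).
    """
    if top_snp not in ld.snp_ids:
        raise ValueError(f"top SNP {top_snp} absent from the LD matrix")
    excluded = {"r2_out_of_range": 0, "weak_instrument": 0, "cap": 0}
    cand = locus[locus["snp"] != top_snp].copy()
    keep = []
    for _, row in cand.iterrows():
        s = row["snp"]
        if s not in ld.snp_ids:
            excluded["r2_out_of_range"] += 1
            continue
        r2 = ld.r2(s, top_snp)
        if not (r2_low < r2 < r2_high):
            excluded["r2_out_of_range"] += 1
            continue
        if row["p"] > p_max:
            excluded["weak_instrument"] += 1
            continue
        keep.append((row["p"], s))
    keep.sort(key=lambda t: (t[0], t[1]))
    if len(keep) > cap:
        excluded["cap"] = len(keep) - cap
        keep = keep[:cap]
    return [s for _, s in keep], excluded


def _d_covariance(b_zx, se_zy, r, ridge: float = 1e-8,
                  se_zx=None, b_zy=None):
    """Covariance of d_i = b_xy_i - b_xy_top; index 0 is the top SNP.

    Default: first-order delta method treating the exposure effects b_zx as
    fixed (valid when the exposure study is large). When ``se_zx`` and
    ``b_zy`` are supplied, the exposure-side sampling term of the ratio is
    added: cov += b_xy_i b_xy_j r_ij se_zx_i se_zx_j / (b_zx_i b_zx_j)
    (the cross zx-zy terms vanish across two independent samples). This is
    needed when the exposure cohort is small, where the fixed-b_zx formula
    is strongly anti-conservative.
    """
    scale = se_zy / b_zx
    cov_xy = r * np.outer(scale, scale)  # cov of the b_xy vector
    if se_zx is not None:
        b_xy = np.asarray(b_zy, dtype=float) / b_zx
        zx_scale = b_xy * np.asarray(se_zx, dtype=float) / b_zx
        cov_xy = cov_xy + r * np.outer(zx_scale, zx_scale)
    k = len(b_zx) - 1
    V = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            i, j = a + 1, b + 1
            V[a, b] = cov_xy[i, j] - cov_xy[i, 0] - cov_xy[j, 0] + cov_xy[0, 0]
    V = V + ridge * np.eye(k)
    eig = np.linalg.eigvalsh(V)
    if eig.min() < -1e-8:
        raise ValueError(
            f"HEIDI covariance not positive semi-definite (min eig {eig.min():.2e})"
        )
    return V


def _satterthwaite_tail(t: float, lam: np.ndarray) -> float:
    """Two-moment scaled-chi-square tail of sum_i lam_i chi2_1."""
    s1, s2 = lam.sum(), (lam**2).sum()
    return float(stats.chi2.sf(t * s1 / s2, df=s1**2 / s2))


def _imhof_tail(t: float, lam: np.ndarray) -> float:
    """Exact tail P(sum_i lam_i chi2_1 > t) by Imhof's inversion integral.

    Falls back to the two-moment approximation when the oscillatory
    integral cannot be evaluated reliably (extreme statistics, where both
    answers are equally decisive).
    """
    lam = np.asarray(lam, dtype=float)

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * t * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return np.sin(theta) * np.exp(-log_rho) / u

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        try:
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=2000)
        except Exception:
            return _satterthwaite_tail(t, lam)
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-4:
        return _satterthwaite_tail(t, lam)
    return min(max(p, 0.0), 1.0)


def heidi_test(
    table: pd.DataFrame,
    ld: LDMatrix,
    top_snp: str,
    cpg: str = "",
    method: str = "imhof",
    n_mc: int = 20000,
    seed: int = 0,
    excluded: Optional[dict] = None,
    account_exposure_noise: bool = False,
) -> HEIDIResult:
    """Compute the HEIDI statistic and p-value.

    ``table`` holds one row per SNP (top SNP included) with columns
    snp, b_zx, se_zy, b_zy (plus se_zx when ``account_exposure_noise``).
    ``method`` selects the exact weighted-chi-square inversion ("imhof",
    default), the Satterthwaite scaled-chi-square approximation
    ("satterthwaite"), or a multivariate-normal Monte-Carlo p ("mc").
    ``account_exposure_noise`` adds the exposure-side sampling variance of
    the ratios, required when the exposure effects come from a small cohort.
    """
    rows = table.set_index("snp")
    others = [s for s in table["snp"] if s != top_snp]
    if len(others) < 1:
        return HEIDIResult(cpg, top_snp, np.nan, np.nan, 0, excluded or {})
    order = [top_snp] + others
    b_zx = rows.loc[order, "b_zx"].to_numpy(dtype=float)
    b_zy = rows.loc[order, "b_zy"].to_numpy(dtype=float)
    se_zy = rows.loc[order, "se_zy"].to_numpy(dtype=float)
    if np.any(b_zx == 0):
        raise ValueError("zero exposure effect in the HEIDI SNP set")
    r = ld.submatrix(order).r
    b_xy = b_zy / b_zx
    d = b_xy[1:] - b_xy[0]
    se_zx = (rows.loc[order, "se_zx"].to_numpy(dtype=float)
             if account_exposure_noise else None)
    V = _d_covariance(b_zx, se_zy, r, se_zx=se_zx,
                      b_zy=b_zy if account_exposure_noise else None)
    sd = np.sqrt(np.diag(V))
    t_stat = float(np.sum((d / sd) ** 2))
    C = V / np.outer(sd, sd)  # correlation matrix of d
    lam = np.linalg.eigvalsh(C)
    lam = lam[lam > 1e-12]
    if method == "imhof":
        p = _imhof_tail(t_stat, lam)
    elif method == "satterthwaite":
        s1, s2 = lam.sum(), (lam**2).sum()
        c = s2 / s1
        nu = s1**2 / s2
        p = float(stats.chi2.sf(t_stat / c, df=nu))
    elif method == "mc":
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(V + 1e-10 * np.eye(len(d)))
        z = rng.standard_normal((n_mc, len(d)))
        sims = ((z @ L.T) / sd) ** 2
        t_sim = sims.sum(axis=1)
        p = float((1 + (t_sim >= t_stat).sum()) / (n_mc + 1))
    else:
        raise ValueError("method must be 'imhof', 'satterthwaite' or 'mc'")
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return HEIDIResult(cpg, top_snp, t_stat, p, len(others), excluded or {})


def classify_pleiotropy_vs_linkage(results, alpha: Optional[float] = None) -> pd.DataFrame:
    """Per-DMC verdict from HEIDI p-values.

    ``alpha`` defaults to the Bonferroni level 0.05 / (number of tested
    loci). p < alpha rejects the shared-causal-variant null -> "linkage";
    otherwise "consistent with single shared causal variant"; untestable loci
    (no eligible SNPs) report NA.
    """
    results = list(results)
    tested = [r for r in results if not r.is_na()]
    if alpha is None:
        alpha = 0.05 / max(len(tested), 1)
    rows = []
    for r in results:
        if r.is_na():
            verdict = "NA"
        elif r.p_heidi < alpha:
            verdict = "linkage"
        else:
            verdict = "consistent with single shared causal variant"
        rows.append({
            "cpg": r.cpg, "top_snp": r.top_snp, "t_stat": r.t_stat,
            "p_heidi": r.p_heidi, "n_snp_heidi": r.n_snp_heidi,
            "alpha": alpha, "verdict": verdict,
        })
    return pd.DataFrame(rows)


class HeidiTest:
    """HEIDI test for one mediator-DMC locus.

    Parameters
    ----------
    exposure : DataFrame of the locus mQTL statistics (snp, b_zx, se_zx, p,
        allele columns).
    outcome : SummaryStats (GWAS side).
    ld : LDMatrix covering the locus.
    top_snp : the causal candidate; defaults to the smallest-p mQTL SNP.
    """

    def __init__(self, exposure: pd.DataFrame, outcome: SummaryStats,
                 ld: LDMatrix, top_snp: Optional[str] = None, cpg: str = "",
                 exposure_alleles: Optional[pd.DataFrame] = None,
                 r2_low: float = 0.05, r2_high: float = 0.9,
                 p_max: float = 1.6e-3, cap: int = 20,
                 account_exposure_noise: bool = False):
        self.account_exposure_noise = account_exposure_noise
        harm = harmonize(exposure, outcome, exposure_alleles)
        pmap = exposure.set_index("snp")["p"]
        harm["p"] = harm["snp"].map(pmap)
        self.table = harm
        self.ld = ld
        self.cpg = cpg
        if top_snp is None and len(harm):
            top_snp = str(harm.loc[harm["p"].idxmin(), "snp"])
        self.top_snp = top_snp
        self.r2_low, self.r2_high = r2_low, r2_high
        self.p_max, self.cap = p_max, cap

    def fit(self, method: str = "imhof", seed: int = 0) -> HEIDIResult:
        if self.top_snp is None or self.table.empty:
            return HEIDIResult(self.cpg, str(self.top_snp), np.nan, np.nan, 0, {})
        snps, excluded = select_heidi_snps(
            self.table, self.top_snp, self.ld,
            self.r2_low, self.r2_high, self.p_max, self.cap,
        )
        if not snps:
            return HEIDIResult(self.cpg, self.top_snp, np.nan, np.nan, 0, excluded)
        sub = self.table[self.table["snp"].isin([self.top_snp] + snps)]
        return heidi_test(sub, self.ld, self.top_snp, cpg=self.cpg,
                          method=method, seed=seed, excluded=excluded,
                          account_exposure_noise=self.account_exposure_noise)
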