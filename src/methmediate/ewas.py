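"""Count-based differential-methylation analysis (EWAS) on RRBS data.

The per-CpG model is a binomial logistic regression on read counts,

    logit(P_i) = b0 + b1 * X_i + sum_j a_j * covariate_{j,i},

where P_i is the proportion of methylated cytosines of subject i, X_i the
phenotype group (0 = low, 1 = high) and b1 the log odds ratio between the
groups. Each subject contributes (methylated, unmethylated) read counts, so
subjects are implicitly weighted by their sequencing coverage. Multiple
testing is controlled by Bonferroni over the tested CpG family, and a CpG is
a differentially methylated CpG (DMC) when it is Bonferroni-significant and
the raw between-group beta-value difference exceeds a configured threshold.

Cell-admixture / batch control follows the principal-component approach: each
CpG's beta-values are inverse-normal transformed, complete CpGs enter a PCA
over subjects, and the leading score is carried as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from methmediate.datatypes import MethylationCounts

__all__ = [
    "filter_cpgs",
    "inverse_normal_transform",
    "methylation_pcs",
    "test_dmc",
    "classify_dmcs",
    "power_simulation",
    "estimate_overdispersion",
    "EWASModel",
    "EWASResults",
]


def filter_cpgs(
    counts: MethylationCounts,
    groups: np.ndarray,
    min_coverage: int = 3,
    min_subjects_per_group: int = 30,
):
    """Retain CpGs covered >= min_coverage in >= min_subjects_per_group
    subjects of EACH phenotype group.

    Returns (filtered_counts, n_retained, n_total).
    """
    groups = np.asarray(groups, dtype=int)
    if counts.n_subjects != len(groups):
        raise ValueError("groups length must match subject count")
    if (groups == 0).sum() == 0 or (groups == 1).sum() == 0:
        raise ValueError("both phenotype groups must be non-empty")
    covered = counts.n >= min_coverage
    n0 = covered[:, groups == 0].sum(axis=1)
    n1 = covered[:, groups == 1].sum(axis=1)
    keep = (n0 >= min_subjects_per_group) & (n1 >= min_subjects_per_group)
    if (groups == 0).sum() < min_subjects_per_group or (groups == 1).sum() < min_subjects_per_group:
        import warnings

        warnings.warn(
            "a group is smaller than min_subjects_per_group; every CpG filtered",
            stacklevel=2,
        )
    return counts.subset_cpgs(np.flatnonzero(keep)), int(keep.sum()), counts.n_cpgs


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^{-1}((rank - 0.5) / m).

    Ranks are tie-averaged over the m non-missing entries; missing entries
    stay missing. Strictly monotone in the input modulo ties.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    obs = ~np.isnan(values)
    m = int(obs.sum())
    if m < 2:
        raise ValueError("need at least 2 non-missing values")
    ranks = stats.rankdata(values[obs], method="average")
    out[obs] = stats.norm.ppf((ranks - 0.5) / m)
    return out


def methylation_pcs(counts: MethylationCounts, k: int, impute_mean: bool = False):
    """Principal components of the (INT-transformed) subject-by-CpG matrix.

    CpGs with any missing value are excluded from the PCA input by default
    (``impute_mean=True`` mean-imputes instead). Returns (scores, varexp):
    scores is subjects x k, varexp the fraction of variance per component.
    """
    beta = counts.beta_values()
    rows = []
    for i in range(beta.shape[0]):
        row = beta[i]
        obs = ~np.isnan(row)
        if obs.sum() < 2:
            continue
        if not obs.all() and not impute_mean:
            continue
        t = inverse_normal_transform(row)
        if impute_mean and np.isnan(t).any():
            t = np.where(np.isnan(t), np.nanmean(t), t)
        rows.append(t)
    if len(rows) < k:
        raise ValueError(f"only {len(rows)} complete CpGs available for {k} PCs")
    X = np.asarray(rows).T  # subjects x CpGs
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    varexp = var / var.sum()
    scores = u[:, :k] * s[:k]
    return scores, varexp[:k]


@dataclass
class DMCResult:
    """Per-CpG differential-methylation fit."""

    cpg: str
    beta1: float
    se_beta1: float
    p: float
    meth_diff: float  # percent, high-group mean beta minus low-group mean beta
    mean_coverage: float
    converged: bool = True
    n_tested: Optional[int] = None

    @property
    def p_bonferroni(self) -> Optional[float]:
        if self.n_tested is None or not np.isfinite(self.p):
            return None
        return min(1.0, self.p * self.n_tested)


def _meth_diff_percent(m, n, group) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(n > 0, m / n, np.nan)
    d = np.nanmean(beta[group == 1]) - np.nanmean(beta[group == 0])
    return float(100.0 * d)


def test_dmc(
    m: np.ndarray,
    n: np.ndarray,
    group: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    cpg: str = "",
) -> DMCResult:
    """Binomial logistic regression of one CpG's counts on the group label.

    Subjects with zero or missing coverage are dropped. Returns the group
    log odds ratio b1, its Wald standard error and two-sided p. Perfect
    separation or non-convergence yields a flagged result with missing p.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    group = np.asarray(group, dtype=float)
    ok = np.isfinite(n) & (n > 0) & np.isfinite(m)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        ok &= np.isfinite(covariates).all(axis=1)
    m, n, group = m[ok], n[ok], group[ok]
    X = group[:, None]
    if covariates is not None:
        # drop constant covariate columns so the design stays full rank
        cov = covariates[ok]
        keep = cov.std(axis=0) > 0
        X = np.column_stack([X, cov[:, keep]])
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1] or m.size == 0:
        return DMCResult(cpg, np.nan, np.nan, np.nan,
                         _meth_diff_percent(m, n, group), float(np.mean(n)) if n.size else np.nan,
                         converged=False)
    endog = np.column_stack([m, n - m])
    diff = _meth_diff_percent(m, n, group)
    cov_mean = float(np.mean(n))
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=100)
        beta1 = float(fit.params[1])
        se1 = float(fit.bse[1])
        if not np.isfinite(se1) or se1 <= 0 or se1 > 1e3 or not fit.converged:
            return DMCResult(cpg, beta1, np.nan, np.nan, diff, cov_mean, converged=False)
        z = beta1 / se1
        p = float(2 * stats.norm.sf(abs(z)))
        return DMCResult(cpg, beta1, se1, max(p, np.finfo(float).tiny), diff, cov_mean)
    except Exception:
        return DMCResult(cpg, np.nan, np.nan, np.nan, diff, cov_mean, converged=False)


def classify_dmcs(
    results: pd.DataFrame,
    alpha: float = 0.05,
    diff_threshold: float = 0.05,
    n_tested: Optional[int] = None,
) -> pd.DataFrame:
    """Select DMCs: Bonferroni-significant AND |meth_diff| past the threshold.

    The absolute-difference rule is a strict ">" at 0.05 and ">=" at 0.10
    (the two reporting thresholds); any other threshold uses strict ">".
    ``meth_diff`` is in percent, ``diff_threshold`` on the 0-1 scale.
    """
    if n_tested is None:
        n_tested = int(np.isfinite(results["p"]).sum())
    if n_tested == 0:
        return results.iloc[0:0]
    sig = results["p"] < alpha / n_tested
    adiff = results["meth_diff"].abs() / 100.0
    if np.isclose(diff_threshold, 0.10):
        big = adiff >= diff_threshold
    else:
        big = adiff > diff_threshold
    return results[sig & big & np.isfinite(results["p"])]


def power_simulation(
    n_low: int,
    n_high: int,
    mean_coverage: float,
    p_low: float,
    diff: float,
    alpha: float = 0.05,
    reps: int = 200,
    seed: int = 0,
    coverage_dispersion: float = 40.0,
):
    """Monte-Carlo power of the count-based logistic test.

    Simulates ``reps`` studies of (n_low + n_high) subjects with NB coverage
    and binomial counts at methylation probability p_low vs p_low + diff, and
    returns (power, binomial SE of the estimate).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    p_high = min(max(p_low + diff, 1e-6), 1 - 1e-6)
    group = np.concatenate([np.zeros(n_low), np.ones(n_high)])
    probs = np.where(group == 1, p_high, p_low)
    size = coverage_dispersion
    p_nb = size / (size + mean_coverage)
    hits = 0
    for _ in range(reps):
        n = rng.negative_binomial(size, p_nb, size=len(group)).astype(float)
        m = rng.binomial(n.astype(int), probs).astype(float)
        res = test_dmc(m, n, group)
        if res.converged and res.p < alpha:
            hits += 1
    power = hits / reps
    return power, float(np.sqrt(power * (1 - power) / reps))


def estimate_overdispersion(m: np.ndarray, n: np.ndarray, group: np.ndarray) -> float:
    """Observed-to-binomial-expected variance ratio of beta-values.

    Within each group the observed variance of m/n is divided by the
    binomial-expected variance mean(p_hat (1 - p_hat) / n); group ratios are
    pooled by a coverage-weighted average. A ratio of ~1 means no
    over-dispersion. Groups with a degenerate pooled p_hat (0 or 1) are
    reported missing.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    group = np.asarray(group, dtype=int)
    ratios, weights = [], []
    for gval in (0, 1):
        sel = (group == gval) & (n > 0) & np.isfinite(m)
        if sel.sum() < 2:
            raise ValueError("need >= 2 covered subjects per group")
        mm, nn = m[sel], n[sel]
        beta = mm / nn
        p_hat = mm.sum() / nn.sum()
        if p_hat <= 0 or p_hat >= 1:
            ratios.append(np.nan)
            weights.append(nn.sum())
            continue
        expected = np.mean(p_hat * (1 - p_hat) / nn)
        observed = beta.var(ddof=1)
        ratios.append(observed / expected)
        weights.append(nn.sum())
    ratios = np.asarray(ratios)
    weights = np.asarray(weights, dtype=float)
    ok = np.isfinite(ratios)
    if not ok.any():
        return float("nan")
    return float(np.average(ratios[ok], weights=weights[ok]))


class EWASModel:
    """Differential-methylation model over a filtered CpG set.

    Parameters
    ----------
    counts : MethylationCounts
    group : array-like of {0, 1}
        Phenotype group per subject (1 = high).
    covariates : DataFrame or ndarray, optional
        Subject-level adjustment covariates (age, BMI, smoking, drinking ...).
    add_meth_pc1 : bool
        Append the first principal component of the INT-normalized
        methylation matrix as a covariate (cell-admixture / batch control).
    """

    def __init__(self, counts, group, covariates=None, add_meth_pc1: bool = True,
                 min_coverage: int = 3, min_subjects_per_group: int = 30):
        group = np.asarray(group, dtype=int)
        filtered, n_kept, n_total = filter_cpgs(
            counts, group, min_coverage, min_subjects_per_group
        )
        self.counts = filtered
        self.group = group
        self.n_filtered_out = n_total - n_kept
        if isinstance(covariates, pd.DataFrame):
            covariates = covariates.to_numpy(dtype=float)
        self.covariates = covariates
        self.meth_pc1 = None
        if add_meth_pc1 and filtered.n_cpgs >= 1:
            try:
                scores, varexp = methylation_pcs(filtered, 1)
                self.meth_pc1 = scores[:, 0]
                self.pc1_varexp = float(varexp[0])
            except ValueError:
                self.meth_pc1 = None

    def design_covariates(self):
        parts = []
        if self.covariates is not None:
            parts.append(np.asarray(self.covariates, dtype=float))
        if self.meth_pc1 is not None:
            parts.append(self.meth_pc1[:, None])
        if not parts:
            return None
        return np.column_stack(parts)

    def fit(self) -> "EWASResults":
        cov = self.design_covariates()
        rows = []
        for i in range(self.counts.n_cpgs):
            res = test_dmc(
                self.counts.m[i],
                self.counts.n[i],
                self.group,
                covariates=cov,
                cpg=self.counts.cpgs["id"].iloc[i],
            )
            rows.append(res)
        n_tested = sum(1 for r in rows if r.converged and np.isfinite(r.p))
        table = pd.DataFrame(
            {
                "cpg": [r.cpg for r in rows],
                "chrom": self.counts.cpgs["chrom"].to_numpy(),
                "pos": self.counts.cpgs["pos"].to_numpy(),
                "beta1": [r.beta1 for r in rows],
                "se": [r.se_beta1 for r in rows],
                "p": [r.p for r in rows],
                "meth_diff": [r.meth_diff for r in rows],
                "mean_cov": [r.mean_coverage for r in rows],
                "converged": [r.converged for r in rows],
            }
        )
        table["p_bonf"] = np.minimum(1.0, table["p"] * n_tested)
        return EWASResults(table, n_tested, self)


class EWASResults:
    """Fitted EWAS: per-CpG statistics and DMC classification."""

    def __init__(self, table: pd.DataFrame, n_tested: int, model: EWASModel):
        self.table = table
        self.n_tested = n_tested
        self.model = model

    def dmcs(self, alpha: float = 0.05, diff_threshold: float = 0.05) -> pd.DataFrame:
        return classify_dmcs(self.table, alpha, diff_threshold, self.n_tested)

    def summary(self) -> str:
        n_dmc05 = len(self.dmcs(diff_threshold=0.05))
        n_dmc10 = len(self.dmcs(diff_threshold=0.10))
        lines = [
            "Differential methylation (binomial logistic regression)",
            f"  CpGs tested (Bonferroni family): {self.n_tested}",
            f"  CpGs dropped by coverage filter: {self.model.n_filtered_out}",
            f"  non-converged fits (excluded):   {int((~self.table['converged']).sum())}",
            f"  DMCs at |diff| > 0.05:           {n_dmc05}",
            f"  DMCs at |diff| >= 0.10:          {n_dmc10}",
            "  meth_diff convention: percent (high minus low group)",
        ]
        return "\n".join(lines)
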