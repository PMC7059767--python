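"""Annotation-aware Bayesian fine-mapping by exhaustive configuration search.

Model (summary-statistics multivariate-normal family): with locus Z-scores z,
ridge-regularized LD matrix S = R + eps*I, and a causal configuration c (at
most ``max_causal`` SNPs), the marginal likelihood is

    z | c  ~  N(0,  S + S[:, c] (w^2 I) S[c, :]),

where w^2 is the prior variance of the non-centrality carried by each causal
SNP. The configuration prior is independent-Bernoulli with logistic per-SNP
probabilities pi_j = logistic(a0 + a' A_j) driven by binary annotations A_j.
Posteriors are computed by exact enumeration over all configurations of size
<= max_causal (the empty configuration included), in log space; the per-SNP
posterior inclusion probability (PIP) sums the posteriors of configurations
containing the SNP. Annotation weights (a0, a) are fitted across loci by EM:
the E-step computes PIPs at the current weights and the M-step fits a
PIP-weighted logistic regression on the annotations.

Likelihood evaluations use the matrix determinant lemma and Woodbury
identity, so each configuration costs O(|c|^3) after one factorization of S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
import statsmodels.api as sm

from methmediate.datatypes import LDMatrix

__all__ = [
    "LocusData",
    "LocusPosterior",
    "config_likelihood",
    "config_prior",
    "enumerate_posteriors",
    "em_fit_annotations",
    "FineMap",
]

DEFAULT_W2 = 25.0   # prior effect variance, ~|z| = 5 signals
DEFAULT_RIDGE = 1e-3


@dataclass
class LocusData:
    """One fine-mapping locus: Z-scores, LD, and annotations."""

    cpg: str
    snps: list
    z: np.ndarray
    sigma: np.ndarray  # LD correlation matrix (un-ridged)
    annotations: Optional[np.ndarray] = None  # SNP x track binary

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if isinstance(self.sigma, LDMatrix):
            self.sigma = self.sigma.r
        self.sigma = np.asarray(self.sigma, dtype=float)
        m = len(self.snps)
        if self.z.shape != (m,) or self.sigma.shape != (m, m):
            raise ValueError("z and sigma must match the SNP list")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("Z-scores must be finite")
        if self.annotations is None:
            self.annotations = np.zeros((m, 0), dtype=int)
        self.annotations = np.asarray(self.annotations)
        if self.annotations.shape[0] != m:
            raise ValueError("annotation rows must match the SNP list")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_tracks(self) -> int:
        return self.annotations.shape[1]


@dataclass
class LocusPosterior:
    """Fine-mapping output for one locus."""

    cpg: str
    snps: list
    configs: list            # tuples of SNP indices, () = empty configuration
    log_post: np.ndarray     # normalized log posterior per configuration
    pip: np.ndarray
    top_causal: Optional[str]
    a0: float
    a: np.ndarray
    log_marginal: float      # log sum over configurations of prior * likelihood

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"snp": self.snps, "pip": self.pip})

    def config_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "config": ["+".join(str(self.snps[j]) for j in c) or "(empty)"
                       for c in self.configs],
            "posterior": np.exp(self.log_post),
        })


class _LocusLikelihood:
    """Caches the base factorization of S = sigma + ridge*I for one locus."""

    def __init__(self, locus: LocusData, ridge: float = DEFAULT_RIDGE):
        S = locus.sigma + ridge * np.eye(locus.n_snps)
        try:
            self.chol = np.linalg.cholesky(S)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "locus covariance not positive definite after ridge"
            ) from err
        self.S = S
        self.z = locus.z
        self.logdet_S = 2.0 * np.log(np.diag(self.chol)).sum()
        u = np.linalg.solve(self.chol, self.z)
        self.base_quad = float(u @ u)  # z' S^-1 z
        m = locus.n_snps
        self.log_norm = -0.5 * (m * np.log(2 * np.pi) + self.logdet_S)

    def loglik(self, c: tuple, w2: float) -> float:
        """Log N(z; 0, S + S[:,c] w2 I S[c,:]) via determinant lemma/Woodbury."""
        if len(c) == 0:
            return self.log_norm - 0.5 * self.base_quad
        idx = np.asarray(c, dtype=int)
        Scc = self.S[np.ix_(idx, idx)]
        k = len(idx)
        # |Sigma_c| = |S| * |I + w2 * Scc|
        M = np.eye(k) + w2 * Scc
        sign, logdet_M = np.linalg.slogdet(M)
        if sign <= 0:
            raise ValueError("configuration covariance not positive definite")
        # z' Sigma_c^-1 z = z'S^-1 z - z_c' (I/w2 + Scc)^-1 z_c
        zc = self.z[idx]
        quad = self.base_quad - float(zc @ np.linalg.solve(np.eye(k) / w2 + Scc, zc))
        m = len(self.z)
        return -0.5 * (m * np.log(2 * np.pi) + self.logdet_S + logdet_M + quad)


def config_likelihood(locus: LocusData, c, w2: float = DEFAULT_W2,
                      ridge: float = DEFAULT_RIDGE) -> float:
    """Log marginal likelihood of one causal configuration (see module doc)."""
    if w2 <= 0:
        raise ValueError("prior effect variance w2 must be positive")
    return _LocusLikelihood(locus, ridge).loglik(tuple(c), w2)


def config_prior(c, annotations: np.ndarray, a0: float, a: np.ndarray) -> float:
    """Log independent-Bernoulli prior of configuration ``c``.

    P(j causal) = logistic(a0 + a' A_j); the log prior sums log pi_j over
    members and log(1 - pi_j) over non-members. (Across an enumeration
    truncated at max_causal the priors are renormalized implicitly by the
    posterior normalization.)
    """
    annotations = np.asarray(annotations, dtype=float)
    a = np.asarray(a, dtype=float)
    if not (np.isfinite(a0) and np.all(np.isfinite(a))):
        raise ValueError("prior weights must be finite")
    eta = a0 + (annotations @ a if annotations.size else np.zeros(annotations.shape[0]))
    # numerically stable log pi and log(1-pi)
    log_pi = -np.logaddexp(0.0, -eta)
    log_1mpi = -np.logaddexp(0.0, eta)
    total = log_1mpi.sum()
    out = total
    for j in c:
        out += log_pi[j] - log_1mpi[j]
    return float(out)


def _log_priors_all(configs, annotations, a0, a):
    annotations = np.asarray(annotations, dtype=float)
    m = annotations.shape[0]
    eta = a0 + (annotations @ np.asarray(a, dtype=float)
                if annotations.shape[1] else np.zeros(m))
    log_pi = -np.logaddexp(0.0, -eta)
    log_1mpi = -np.logaddexp(0.0, eta)
    base = log_1mpi.sum()
    out = np.empty(len(configs))
    for i, c in enumerate(configs):
        v = base
        for j in c:
            v += log_pi[j] - log_1mpi[j]
        out[i] = v
    return out


def _all_configs(m: int, max_causal: int):
    configs = [()]
    for k in range(1, max_causal + 1):
        configs.extend(combinations(range(m), k))
    return configs


def enumerate_posteriors(
    locus: LocusData,
    a0: float = None,
    a: Optional[np.ndarray] = None,
    max_causal: int = 2,
    w2: float = DEFAULT_W2,
    ridge: float = DEFAULT_RIDGE,
    max_snps: int = 1000,
) -> LocusPosterior:
    """Exact posterior over all causal configurations with |c| <= max_causal.

    Default prior: a0 = logit(1/m) so one causal SNP is expected a priori
    when no annotation weights are supplied.
    """
    m = locus.n_snps
    if m > max_snps:
        raise ValueError(
            f"locus has {m} SNPs > cap {max_snps}; pre-filter the locus"
        )
    if a0 is None:
        a0 = float(np.log(1.0 / m / (1 - 1.0 / m)))
    if a is None:
        a = np.zeros(locus.n_tracks)
    ll = _LocusLikelihood(locus, ridge)
    configs = _all_configs(m, max_causal)
    log_lik = np.array([ll.loglik(c, w2) for c in configs])
    log_prior = _log_priors_all(configs, locus.annotations, a0, a)
    log_joint = log_lik + log_prior
    log_marg = float(logsumexp(log_joint))
    log_post = log_joint - log_marg
    pip = np.zeros(m)
    post = np.exp(log_post)
    for c, pp in zip(configs, post):
        for j in c:
            pip[j] += pp
    top = locus.snps[int(np.argmax(pip))] if m else None
    return LocusPosterior(locus.cpg, list(locus.snps), configs, log_post,
                          pip, top, a0, np.asarray(a, dtype=float), log_marg)


def em_fit_annotations(
    loci: list,
    max_iter: int = 100,
    tol: float = 1e-4,
    max_causal: int = 2,
    w2: float = DEFAULT_W2,
    ridge: float = DEFAULT_RIDGE,
    weight_cap: float = 10.0,
):
    """Empirical-Bayes fit of the annotation prior weights across loci.

    E-step: PIPs per locus at the current (a0, a). M-step: logistic
    regression of the PIPs on the annotations (fractional binomial GLM).
    Iterates until the largest weight change drops below ``tol``. The
    marginal log-likelihood (sum over loci of the log enumeration mass) is
    non-decreasing across iterations and asserted so.

    Returns (a0, a, history) with history the marginal log-likelihood path.
    """
    if not loci:
        raise ValueError("need at least one locus")
    n_tracks = loci[0].n_tracks
    total_snps = sum(l.n_snps for l in loci)
    if total_snps < n_tracks + 1:
        raise ValueError("more annotation tracks than SNPs")
    m_mean = np.mean([l.n_snps for l in loci])
    a0 = float(np.log(1.0 / m_mean / (1 - 1.0 / m_mean)))
    a = np.zeros(n_tracks)
    caches = [_LocusLikelihood(l, ridge) for l in loci]
    configs_per = [_all_configs(l.n_snps, max_causal) for l in loci]
    logliks = [np.array([c.loglik(cfg, w2) for cfg in cfgs])
               for c, cfgs in zip(caches, configs_per)]

    def marginal(a0_, a_):
        tot = 0.0
        for l, cfgs, ll in zip(loci, configs_per, logliks):
            lp = _log_priors_all(cfgs, l.annotations, a0_, a_)
            tot += logsumexp(ll + lp)
        return tot

    history = [marginal(a0, a)]
    for _ in range(max_iter):
        # E-step
        pips, anns = [], []
        for l, cfgs, ll in zip(loci, configs_per, logliks):
            lp = _log_priors_all(cfgs, l.annotations, a0, a)
            w = ll + lp
            w = np.exp(w - logsumexp(w))
            pip = np.zeros(l.n_snps)
            for cfg, pp in zip(cfgs, w):
                for j in cfg:
                    pip[j] += pp
            pips.append(np.clip(pip, 1e-12, 1 - 1e-12))
            anns.append(l.annotations)
        y = np.concatenate(pips)
        X = sm.add_constant(np.vstack(anns).astype(float), has_constant="add")
        # M-step: fractional logistic regression of PIPs on annotations
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            params = np.asarray(fit.params, dtype=float)
        except Exception:
            params = np.concatenate([[a0], a])
        if np.any(np.abs(params) > weight_cap):
            warnings.warn("annotation weight clipped at |a| <= 10 (separation)",
                          stacklevel=2)
            params = np.clip(params, -weight_cap, weight_cap)
        new_a0, new_a = float(params[0]), params[1:]
        delta = max(abs(new_a0 - a0),
                    float(np.max(np.abs(new_a - a))) if n_tracks else 0.0)
        a0, a = new_a0, new_a
        ml = marginal(a0, a)
        assert ml >= history[-1] - 1e-8, "EM marginal likelihood decreased"
        history.append(ml)
        if delta < tol:
            break
    return a0, a, history


class FineMap:
    """Fine-mapping model over one or more mediator-DMC loci.

    Parameters
    ----------
    loci : list of LocusData
    max_causal : at most this many causal SNPs per configuration (default 2).
    w2 : prior non-centrality variance per causal SNP.
    fit_annotations : learn (a0, a) by EM across loci; otherwise the
        intercept-only prior a0 = logit(1/m) is used per locus.
    """

    def __init__(self, loci, max_causal: int = 2, w2: float = DEFAULT_W2,
                 ridge: float = DEFAULT_RIDGE, fit_annotations: bool = True):
        self.loci = list(loci)
        self.max_causal = max_causal
        self.w2 = w2
        self.ridge = ridge
        self.fit_annotations = fit_annotations

    def fit(self) -> "FineMapResults":
        a0, a, history = None, None, []
        n_tracks = self.loci[0].n_tracks if self.loci else 0
        if self.fit_annotations and self.loci:
            a0, a, history = em_fit_annotations(
                self.loci, max_causal=self.max_causal, w2=self.w2,
                ridge=self.ridge,
            )
        posteriors = [
            enumerate_posteriors(l, a0=a0, a=a, max_causal=self.max_causal,
                                 w2=self.w2, ridge=self.ridge)
            for l in self.loci
        ]
        return FineMapResults(posteriors, a0, a, history, n_tracks)


class FineMapResults:
    def __init__(self, posteriors, a0, a, em_history, n_tracks):
        self.posteriors = posteriors
        self.a0 = a0
        self.a = a
        self.em_history = em_history
        self.n_tracks = n_tracks

    def causal_mqtls(self) -> pd.DataFrame:
        """The top-PIP SNP per locus (the causal mQTL call)."""
        rows = []
        for p in self.posteriors:
            pip = float(np.max(p.pip)) if len(p.pip) else np.nan
            rows.append({"cpg": p.cpg, "top_causal": p.top_causal, "pip": pip})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Fine-mapping (exhaustive <=2-causal enumeration)"]
        if self.a0 is not None:
            lines.append(f"  fitted baseline a0 = {self.a0:.3f}")
            for t, w in enumerate(np.atleast_1d(self.a) if self.a is not None else []):
                lines.append(f"  track {t}: weight a = {w:+.3f} (odds x{np.exp(w):.2f})")
        for _, r in self.causal_mqtls().iterrows():
            lines.append(f"  {r['cpg']}: causal mQTL {r['top_causal']} (PIP {r['pip']:.3f})")
        return "\n".join(lines)
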