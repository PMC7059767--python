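"""Two-sample Mendelian randomization of methylation on the trait.

Given per-instrument effects on the exposure (mQTL betas, b_zx) from the
methylation cohort and on the outcome (GWAS betas, b_zy) from an independent
cohort, the causal effect b_xy of methylation on the trait is estimated by:

* the Wald ratio (single instrument): b_xy = b_zy / b_zx,
* inverse-variance weighted (IVW) regression: zero-intercept weighted
  regression of b_zy on b_zx with weights 1/se_zy^2, in fixed-effect or
  multiplicative-random-effect flavour,
* Egger regression (free intercept; intercept = average directional
  pleiotropy; valid under the InSIDE condition),
* the weighted median of per-instrument ratios (robust to <50% invalid
  instruments by weight),
* profile maximum likelihood treating (b_zx_j, b_zy_j) as independent
  normals around (gamma_j, beta * gamma_j).

Instrument sets are LD-pruned to r^2 < 0.2 before estimation, and a
Benjamini-Hochberg FDR across the DMC family defines mediator DMCs.
Reverse causation is probed by one-sample two-stage least squares of
methylation on the genetically predicted trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats, optimize
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from methmediate.datatypes import LDMatrix, SummaryStats

__all__ = [
    "harmonize",
    "prune_ld",
    "steiger_orientation",
    "steiger_locus_orientation",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "max_likelihood",
    "select_mediators",
    "reverse_mr_2sls",
    "MendelianRandomization",
    "MRResult",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
PALINDROME_EAF_WINDOW = (0.42, 0.58)


@dataclass
class MRResult:
    """Causal-effect estimate for one DMC by one method."""

    cpg: str
    method: str
    n_snp: int
    b_xy: float
    se: float
    p: float
    q: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    top_snp: Optional[str] = None
    note: str = ""

    def is_na(self) -> bool:
        return not np.isfinite(self.b_xy)


def _na_result(cpg, method, n_snp, note="") -> MRResult:
    return MRResult(cpg, method, n_snp, np.nan, np.nan, np.nan, note=note)


# ---------------------------------------------------------------------------
# Harmonization and instrument selection


def harmonize(exposure: pd.DataFrame, outcome: SummaryStats,
              exposure_alleles: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    ``exposure`` needs columns snp, b_zx, se_zx, p; allele labels come either
    from columns effect_allele/other_allele on ``exposure`` or from the
    separate ``exposure_alleles`` table (id, effect_allele, other_allele).

    Rules: matching alleles pass through; swapped alleles flip the outcome
    beta's sign; strand flips are resolved through base complements;
    palindromic (A/T, C/G) SNPs are dropped when the outcome EAF lies in
    [0.42, 0.58] and otherwise aligned by EAF. Irreconcilable allele sets
    drop the instrument with a logged reason.
    """
    if exposure_alleles is not None:
        al = exposure_alleles.set_index("id")
    else:
        al = exposure.set_index("snp")[["effect_allele", "other_allele"]]
    out_t = outcome.table.set_index("id")
    rows = []
    for _, r in exposure.iterrows():
        snp = r["snp"]
        if snp not in out_t.index or snp not in al.index:
            warnings.warn(f"{snp}: absent from outcome GWAS; dropped", stacklevel=2)
            continue
        ea, oa = al.loc[snp, "effect_allele"], al.loc[snp, "other_allele"]
        o = out_t.loc[snp]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        b_zy, eaf = float(o["beta_zy"]), float(o["eaf"])
        pal = frozenset((ea, oa)) in _PALINDROMIC
        flip = None
        if pal:
            # a strand flip is textually identical to an allele swap for
            # palindromic SNPs, so label agreement is uninformative; the
            # orientation must come from the allele frequency
            lo, hi = PALINDROME_EAF_WINDOW
            if lo <= eaf <= hi:
                warnings.warn(f"{snp}: palindromic with ambiguous EAF; dropped",
                              stacklevel=2)
                continue
            if (ea, oa) == (o_ea, o_oa):
                flip = False
            elif (ea, oa) == (o_oa, o_ea):
                flip = True
        elif (ea, oa) == (o_ea, o_oa):
            flip = False
        elif (ea, oa) == (o_oa, o_ea):
            flip = True
        else:
            cea, coa = _COMPLEMENT.get(o_ea), _COMPLEMENT.get(o_oa)
            if (ea, oa) == (cea, coa):
                flip = False
            elif (ea, oa) == (coa, cea):
                flip = True
        if flip is None:
            warnings.warn(f"{snp}: irreconcilable alleles; dropped", stacklevel=2)
            continue
        rows.append({
            "snp": snp,
            "b_zx": float(r["b_zx"]),
            "se_zx": float(r["se_zx"]),
            "p_zx": float(r["p"]),
            "b_zy": -b_zy if flip else b_zy,
            "se_zy": float(o["se_zy"]),
            "eaf": 1 - eaf if flip else eaf,
            "palindromic": pal,
        })
    return pd.DataFrame(
        rows, columns=["snp", "b_zx", "se_zx", "p_zx", "b_zy", "se_zy", "eaf",
                       "palindromic"],
    )


def prune_ld(instruments: pd.DataFrame, ld: LDMatrix, r2_max: float = 0.2,
             positions: Optional[dict] = None) -> pd.DataFrame:
    """Greedy LD pruning: keep instruments in ascending exposure-p order,
    accepting a candidate iff r^2 < r2_max against every kept SNP.

    Ties in p break deterministically by (p, position, id).
    """
    if instruments.empty:
        return instruments
    df = instruments.copy()
    df["_pos"] = [positions.get(s, 0) if positions else 0 for s in df["snp"]]
    df = df.sort_values(["p_zx", "_pos", "snp"], kind="mergesort")
    kept = []
    for _, row in df.iterrows():
        s = row["snp"]
        if all(ld.r2(s, k) < r2_max for k in kept):
            kept.append(s)
    out = instruments[instruments["snp"].isin(kept)].copy()
    order = {s: i for i, s in enumerate(kept)}
    return out.sort_values("snp", key=lambda c: c.map(order)).reset_index(drop=True)


def steiger_orientation(g: np.ndarray, exposure: np.ndarray,
                        trait: np.ndarray) -> np.ndarray:
    """Per-SNP causal orientation by the Steiger criterion (one-sample).

    A SNP is exposure-first (a valid instrument for exposure -> trait MR)
    when it explains more of the exposure than of the trait within the same
    cohort: |corr(G, exposure)| > |corr(G, trait)|. Under reverse causation
    (trait -> exposure) the inequality flips for every SNP, because the
    G-exposure correlation is then the G-trait correlation attenuated by the
    trait-exposure correlation. Correlations are pairwise-complete.

    Returns a boolean array, True = exposure-first.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    exposure = np.asarray(exposure, dtype=float)
    trait = np.asarray(trait, dtype=float)
    out = np.zeros(g.shape[1], dtype=bool)
    for j in range(g.shape[1]):
        ok = np.isfinite(g[:, j]) & np.isfinite(exposure) & np.isfinite(trait)
        if ok.sum() < 3 or g[ok, j].std() == 0:
            continue
        r_gx = np.corrcoef(g[ok, j], exposure[ok])[0, 1]
        r_gy = np.corrcoef(g[ok, j], trait[ok])[0, 1]
        out[j] = abs(r_gx) > abs(r_gy)
    return out


def steiger_locus_orientation(g: np.ndarray, exposure: np.ndarray,
                              trait: np.ndarray) -> bool:
    """Locus-level Steiger orientation: pooled over an instrument set.

    Compares the in-sample R-squared of the joint OLS of exposure on all
    instrument dosages against the R-squared of the trait on the same
    dosages. True = exposure-first (the set explains the exposure better).
    Pooling is far more reliable than per-SNP sign comparisons because the
    two fits share the design matrix, so their sampling errors largely
    cancel in the difference. Complete cases only.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    exposure = np.asarray(exposure, dtype=float)
    trait = np.asarray(trait, dtype=float)
    ok = np.isfinite(exposure) & np.isfinite(trait) & np.isfinite(g).all(axis=1)
    if ok.sum() <= g.shape[1] + 1:
        return False

    def r2(v):
        X = np.column_stack([np.ones(int(ok.sum())), g[ok]])
        beta, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
        resid = v[ok] - X @ beta
        tss = ((v[ok] - v[ok].mean()) ** 2).sum()
        return 1.0 - (resid @ resid) / tss if tss > 0 else 0.0

    return r2(exposure) > r2(trait)


# ---------------------------------------------------------------------------
# Estimators


def wald_ratio(inst: pd.Series, cpg: str = "", second_order: bool = False) -> MRResult:
    """Single-instrument causal estimate b_zy / b_zx with delta-method se."""
    b_zx, b_zy = float(inst["b_zx"]), float(inst["b_zy"])
    se_zy = float(inst["se_zy"])
    if b_zx == 0:
        raise ValueError("Wald ratio undefined: exposure effect is zero")
    b = b_zy / b_zx
    if second_order:
        se_zx = float(inst["se_zx"])
        se = np.sqrt(se_zy**2 / b_zx**2 + b_zy**2 * se_zx**2 / b_zx**4)
    else:
        se = se_zy / abs(b_zx)
    p = 2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan
    return MRResult(cpg, "wald_ratio", 1, b, se, p, top_snp=inst.get("snp"))


def _top_snp(instruments: pd.DataFrame) -> Optional[str]:
    if "p_zx" in instruments and len(instruments):
        return str(instruments.loc[instruments["p_zx"].idxmin(), "snp"])
    return None


def ivw(instruments: pd.DataFrame, mode: str = "fixed", cpg: str = "",
        rho: Optional[np.ndarray] = None,
        exposure_error: bool = False) -> MRResult:
    """Inverse-variance weighted regression (zero intercept, weights 1/se_zy^2).

    ``fixed``: residual variance forced to 1 (fixed-effect). ``mre``:
    multiplicative random effects, se scaled by sqrt(max(1, Q/(n-1))).

    ``rho``: signed instrument correlation matrix (same order as the rows).
    When given, the estimator is generalized least squares with outcome
    covariance Omega = rho * outer(se_zy, se_zy) (Burgess-style
    correlated-instrument IVW); residual LD that survives pruning otherwise
    leaves the reported standard error anti-conservative.

    ``exposure_error``: second-order weights, per-SNP variance
    se_zy^2 + b^2 * se_zx^2, iteratively reweighted. First-order weights
    understate the variance whenever the exposure sample is much smaller
    than the outcome sample (b_zx error dominates the ratio's noise).
    """
    k = len(instruments)
    if k < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio for one")
    bx = instruments["b_zx"].to_numpy(dtype=float)
    by = instruments["b_zy"].to_numpy(dtype=float)
    se_zy = instruments["se_zy"].to_numpy(dtype=float)
    se_zx = (instruments["se_zx"].to_numpy(dtype=float)
             if exposure_error else np.zeros(k))
    b = 0.0
    for _ in range(4 if exposure_error else 1):
        var_i = se_zy**2 + b**2 * se_zx**2
        if rho is None:
            w = 1.0 / var_i
            b = (w * bx * by).sum() / (w * bx * bx).sum()
            se_fixed = np.sqrt(1.0 / (w * bx * bx).sum())
            q = float((w * (by - b * bx) ** 2).sum())
        else:
            omega = np.asarray(rho, dtype=float) * (
                np.outer(se_zy, se_zy) + b**2 * np.outer(se_zx, se_zx))
            omega += 1e-12 * np.mean(np.diag(omega)) * np.eye(k)
            oi_bx = np.linalg.solve(omega, bx)
            denom = float(bx @ oi_bx)
            b = float(by @ oi_bx) / denom
            se_fixed = np.sqrt(1.0 / denom)
            resid = by - b * bx
            q = float(resid @ np.linalg.solve(omega, resid))
    if mode == "fixed":
        se = se_fixed
    elif mode == "mre":
        se = se_fixed * np.sqrt(max(1.0, q / (k - 1)))
    else:
        raise ValueError("mode must be 'fixed' or 'mre'")
    p = 2 * stats.norm.sf(abs(b / se))
    method = "ivw_fe" if mode == "fixed" else "ivw_mre"
    res = MRResult(cpg, method, k, float(b), float(se), float(p),
                   top_snp=_top_snp(instruments))
    res.note = f"Q={q:.4g}"
    return res


def egger(instruments: pd.DataFrame, cpg: str = "") -> MRResult:
    """Egger regression: weighted regression of b_zy on b_zx with intercept.

    Instruments are oriented so b_zx >= 0. The slope estimates the causal
    effect under InSIDE; the intercept the average directional pleiotropy.
    Needs >= 3 instruments; fewer yield an NA result (reporting convention
    for sparse loci).
    """
    k = len(instruments)
    if k < 3:
        return _na_result(cpg, "egger", k, note="fewer than 3 instruments")
    sign = np.sign(instruments["b_zx"].to_numpy(dtype=float))
    sign[sign == 0] = 1.0
    bx = instruments["b_zx"].to_numpy(dtype=float) * sign
    by = instruments["b_zy"].to_numpy(dtype=float) * sign
    w = 1.0 / instruments["se_zy"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones(k), bx])
    fit = sm.WLS(by, X, weights=w).fit()
    slope, slope_se = float(fit.params[1]), float(fit.bse[1])
    inter, inter_se = float(fit.params[0]), float(fit.bse[0])
    df = k - 2
    p_slope = 2 * stats.t.sf(abs(slope / slope_se), df=df)
    p_inter = 2 * stats.t.sf(abs(inter / inter_se), df=df)
    return MRResult(cpg, "egger", k, slope, slope_se, float(p_slope),
                    egger_intercept=inter, egger_intercept_p=float(p_inter),
                    top_snp=_top_snp(instruments))


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0, cpg: str = "") -> MRResult:
    """Weighted median of per-instrument ratios, bootstrap standard error.

    Weights are the inverse first-order variances of the ratio estimates.
    Consistent when instruments carrying >= 50% of the weight are valid.
    """
    k = len(instruments)
    if k < 3:
        return _na_result(cpg, "weighted_median", k, note="fewer than 3 instruments")
    bx = instruments["b_zx"].to_numpy(dtype=float)
    by = instruments["b_zy"].to_numpy(dtype=float)
    sy = instruments["se_zy"].to_numpy(dtype=float)
    sx = instruments["se_zx"].to_numpy(dtype=float)

    def wmed(bx_, by_):
        ratios = by_ / bx_
        var = sy**2 / bx_**2
        w = 1.0 / var
        order = np.argsort(ratios)
        r_sorted, w_sorted = ratios[order], w[order]
        cum = np.cumsum(w_sorted) - 0.5 * w_sorted
        cum /= w_sorted.sum()
        return float(np.interp(0.5, cum, r_sorted))

    est = wmed(bx, by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b[bx_b == 0] = 1e-12
        boots[b] = wmed(bx_b, by_b)
    se = float(boots.std(ddof=1))
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    return MRResult(cpg, "weighted_median", k, est, se, float(p),
                    top_snp=_top_snp(instruments))


def _ml_profile_negloglik(beta, bx, by, sx2, sy2):
    # profile out the per-instrument true exposure effects gamma_j
    gamma = (bx / sx2 + beta * by / sy2) / (1.0 / sx2 + beta**2 / sy2)
    return 0.5 * np.sum((bx - gamma) ** 2 / sx2 + (by - beta * gamma) ** 2 / sy2)


def max_likelihood(instruments: pd.DataFrame, cpg: str = "") -> MRResult:
    """Profile maximum-likelihood causal estimate.

    Model: observed (b_zx_j, b_zy_j) independent normals around
    (gamma_j, beta * gamma_j) with known variances; gamma_j are profiled out
    and beta maximizes the profile likelihood. The standard error comes from
    the numerical curvature of the profile log-likelihood.
    """
    k = len(instruments)
    if k < 2:
        raise ValueError("maximum likelihood needs >= 2 instruments")
    bx = instruments["b_zx"].to_numpy(dtype=float)
    by = instruments["b_zy"].to_numpy(dtype=float)
    sx2 = np.maximum(instruments["se_zx"].to_numpy(dtype=float) ** 2, 1e-12)
    sy2 = instruments["se_zy"].to_numpy(dtype=float) ** 2

    start = float(np.sum(bx * by / sy2) / np.sum(bx * bx / sy2))
    try:
        res = optimize.minimize_scalar(
            _ml_profile_negloglik, args=(bx, by, sx2, sy2),
            bracket=(start - 1.0, start, start + 1.0), method="brent",
            options={"xtol": 1e-10},
        )
    except ValueError:
        # the IVW start need not bracket the profile minimum; fall back to a
        # wide bounded search
        half = 10.0 * (1.0 + abs(start))
        res = optimize.minimize_scalar(
            _ml_profile_negloglik, args=(bx, by, sx2, sy2),
            bounds=(start - half, start + half), method="bounded",
            options={"xatol": 1e-10},
        )
    if not res.success or not np.isfinite(res.x):
        return _na_result(cpg, "max_likelihood", k, note="optimizer failed")
    beta = float(res.x)
    h = max(1e-5, 1e-5 * abs(beta))
    f0 = _ml_profile_negloglik(beta, bx, by, sx2, sy2)
    fp = _ml_profile_negloglik(beta + h, bx, by, sx2, sy2)
    fm = _ml_profile_negloglik(beta - h, bx, by, sx2, sy2)
    info = (fp - 2 * f0 + fm) / h**2
    if info <= 0:
        return _na_result(cpg, "max_likelihood", k, note="non-positive information")
    se = float(1.0 / np.sqrt(info))
    p = 2 * stats.norm.sf(abs(beta / se))
    return MRResult(cpg, "max_likelihood", k, beta, se, float(p),
                    top_snp=_top_snp(instruments))


# ---------------------------------------------------------------------------
# FDR selection across DMCs


def select_mediators(primary_results: list, fdr_q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg over the primary result of every DMC.

    Returns the full table with q-values and a mediator flag (q < fdr_q).
    """
    rows = [r for r in primary_results if np.isfinite(r.p)]
    table = pd.DataFrame({
        "cpg": [r.cpg for r in primary_results],
        "method": [r.method for r in primary_results],
        "n_snp": [r.n_snp for r in primary_results],
        "b_xy": [r.b_xy for r in primary_results],
        "se": [r.se for r in primary_results],
        "p": [r.p for r in primary_results],
        "top_snp": [r.top_snp for r in primary_results],
    })
    table["q"] = np.nan
    finite = np.isfinite(table["p"].to_numpy(dtype=float))
    if finite.any():
        _, qvals, _, _ = multipletests(table.loc[finite, "p"], method="fdr_bh")
        table.loc[finite, "q"] = qvals
    table["mediator"] = table["q"] < fdr_q
    for r, q in zip([p for p, f in zip(primary_results, finite) if f],
                    table.loc[finite, "q"]):
        r.q = float(q)
    return table


# ---------------------------------------------------------------------------
# Reverse-direction one-sample 2SLS


@dataclass
class TwoSLSResult:
    coef: float
    se: float
    p: float
    stage1_f: float
    mode: str
    weak_instruments: bool = False


def reverse_mr_2sls(g_iv: np.ndarray, trait: np.ndarray, meth_m: np.ndarray,
                    meth_n: Optional[np.ndarray] = None,
                    mode: str = "linear") -> TwoSLSResult:
    """Two-stage least squares of methylation on the genetically predicted trait.

    Stage 1 regresses the trait jointly on all instruments; stage 2 regresses
    methylation on the fitted trait values. ``mode="linear"`` treats
    ``meth_m`` as a continuous (e.g. INT-transformed) methylation value;
    ``mode="logistic"`` fits a binomial GLM on (meth_m, meth_n) counts.
    Stage-2 standard errors carry no small-sample IV correction.
    """
    g_iv = np.asarray(g_iv, dtype=float)
    if g_iv.ndim == 1:
        g_iv = g_iv[:, None]
    trait = np.asarray(trait, dtype=float)
    ok = np.isfinite(trait) & np.isfinite(g_iv).all(axis=1)
    if mode == "linear":
        y2 = np.asarray(meth_m, dtype=float)
        ok &= np.isfinite(y2)
    else:
        m = np.asarray(meth_m, dtype=float)
        n = np.asarray(meth_n, dtype=float)
        ok &= np.isfinite(m) & np.isfinite(n) & (n > 0)
    X1 = sm.add_constant(g_iv[ok])
    s1 = sm.OLS(trait[ok], X1).fit()
    k = g_iv.shape[1]
    f = float(s1.fvalue) if np.isfinite(s1.fvalue) else 0.0
    weak = f < 10
    if weak:
        warnings.warn(f"stage-1 F = {f:.2f} < 10: weak instruments", stacklevel=2)
    fitted = s1.fittedvalues
    X2 = sm.add_constant(fitted)
    if mode == "linear":
        s2 = sm.OLS(y2[ok], X2).fit()
        coef, se = float(s2.params[1]), float(s2.bse[1])
        p = float(s2.pvalues[1])
    elif mode == "logistic":
        endog = np.column_stack([m[ok], n[ok] - m[ok]])
        s2 = sm.GLM(endog, X2, family=sm.families.Binomial()).fit()
        coef, se = float(s2.params[1]), float(s2.bse[1])
        p = float(2 * stats.norm.sf(abs(coef / se)))
    else:
        raise ValueError("mode must be 'linear' or 'logistic'")
    return TwoSLSResult(coef, se, p, f, mode, weak)


# ---------------------------------------------------------------------------
# Model facade


class MendelianRandomization:
    """Two-sample MR for one DMC.

    Parameters
    ----------
    exposure : DataFrame with columns snp, b_zx, se_zx, p (mQTL estimates)
        plus allele columns, or provide ``exposure_alleles`` separately.
    outcome : SummaryStats
    ld : LDMatrix covering the exposure SNPs (for pruning); optional when
        instruments are already independent.
    cpg : identifier carried into results.
    """

    def __init__(self, exposure: pd.DataFrame, outcome: SummaryStats,
                 ld: Optional[LDMatrix] = None, cpg: str = "",
                 exposure_alleles: Optional[pd.DataFrame] = None,
                 r2_max: float = 0.2, positions: Optional[dict] = None):
        self.cpg = cpg
        harm = harmonize(exposure, outcome, exposure_alleles)
        if ld is not None and len(harm) > 1:
            harm = prune_ld(harm, ld, r2_max, positions)
        self.instruments = harm
        # residual signed LD among the kept instruments, fed to the
        # correlated-instrument IVW; None when no LD panel was supplied
        self._rho = None
        if ld is not None and len(harm) > 1:
            try:
                self._rho = ld.submatrix(list(harm["snp"])).r
            except KeyError:
                self._rho = None

    def fit(self, method: str = "primary", seed: int = 0) -> MRResult:
        """Estimate b_xy.

        ``method="primary"`` routes a single instrument to the Wald ratio and
        two or more to fixed-effect IVW; other choices: ivw_fe, ivw_mre,
        egger, weighted_median, max_likelihood, wald_ratio.
        """
        inst = self.instruments
        k = len(inst)
        if k == 0:
            return _na_result(self.cpg, method, 0, note="no instruments")
        if method == "primary":
            method = "wald_ratio" if k == 1 else "ivw_fe"
        if method == "wald_ratio":
            if k != 1:
                inst = inst.loc[[inst["p_zx"].idxmin()]]
            return wald_ratio(inst.iloc[0], cpg=self.cpg)
        if method == "ivw_fe":
            return ivw(inst, "fixed", cpg=self.cpg, rho=self._rho,
                       exposure_error=True) if k >= 2 else wald_ratio(inst.iloc[0], cpg=self.cpg)
        if method == "ivw_mre":
            return ivw(inst, "mre", cpg=self.cpg, rho=self._rho,
                       exposure_error=True) if k >= 2 else wald_ratio(inst.iloc[0], cpg=self.cpg)
        if method == "egger":
            return egger(inst, cpg=self.cpg)
        if method == "weighted_median":
            return weighted_median(inst, seed=seed, cpg=self.cpg)
        if method == "max_likelihood":
            if k < 2:
                return _na_result(self.cpg, method, k, note="needs >= 2 instruments")
            return max_likelihood(inst, cpg=self.cpg)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, seed: int = 0) -> pd.DataFrame:
        """Primary plus every sensitivity estimator, as one tidy table."""
        out = [self.fit("primary", seed=seed)]
        for meth in ("ivw_mre", "egger", "weighted_median", "max_likelihood"):
            try:
                out.append(self.fit(meth, seed=seed))
            except ValueError:
                out.append(_na_result(self.cpg, meth, len(self.instruments)))
        return pd.DataFrame([{
            "cpg": r.cpg, "method": r.method, "n_snp": r.n_snp, "b_xy": r.b_xy,
            "se": r.se, "p": r.p, "egger_intercept": r.egger_intercept,
            "egger_intercept_p": r.egger_intercept_p, "top_snp": r.top_snp,
        } for r in out])

    def summary(self, seed: int = 0) -> str:
        tab = self.fit_all(seed=seed)
        lines = [f"Two-sample MR, DMC {self.cpg} ({len(self.instruments)} instruments after pruning)"]
        for _, r in tab.iterrows():
            if np.isfinite(r["b_xy"]):
                lines.append(
                    f"  {r['method']:<16} b_xy={r['b_xy']:+.4f} se={r['se']:.4f} p={r['p']:.3g}"
                )
            else:
                lines.append(f"  {r['method']:<16} NA")
        return "\n".join(lines)
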