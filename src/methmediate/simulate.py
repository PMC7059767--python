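"""Synthetic-cohort generator for the methylation-mediation framework.

Generates, under one of four generative causal models (plus a null), all the
data the pipeline consumes:

* a SNP panel with block LD structure (latent-Gaussian-threshold haplotypes),
* RRBS-style per-CpG methylated/total read counts with negative-binomial
  coverage and optional subject-level over-dispersion on the logit scale,
* an extreme-phenotype methylation cohort (tails of the trait Z distribution),
* an independent outcome-GWAS cohort summarized to per-SNP marginal effects,
* binary annotation tracks enriched (or not) for the true causal SNPs.

Scenarios
---------
mediation   G -> M -> Y: the trait is driven by the latent methylation level.
linkage     G_a -> M and G_b -> Y with G_a, G_b in LD (configured dosage r2).
pleiotropy  G -> M and G -> Y through two independent pathways.
reverse     G -> Y -> M: methylation responds to the trait.
null        no genetic or methylation effects anywhere.

All randomness flows from ``SimulationConfig.seed`` through spawned
``numpy.random.SeedSequence`` streams, so the methylation cohort and the
outcome-GWAS cohort are independent by construction and every output is
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from methmediate.datatypes import (
    GenotypeMatrix,
    MethylationCounts,
    PhenotypeTable,
    SummaryStats,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_annotations",
    "simulate_dataset",
    "latent_rho_for_dosage_corr",
]

SCENARIOS = ("mediation", "linkage", "pleiotropy", "reverse", "null")

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study design.

    The defaults encode the reference study conditions: a methylation cohort
    of 150 extreme-phenotype subjects, an outcome GWAS of 50,000 subjects,
    five independent instrument loci with genotype->methylation effect 0.8
    (logit units per allele) and methylation->trait effect 0.3 (trait SD per
    logit unit), RRBS mean coverage 46.52x, and extreme-group recruitment at
    trait Z-score +/-0.8.
    """

    n_subjects: int = 150
    n_outcome_gwas: int = 50_000
    n_snps: int = 30
    n_cpgs: int = 50
    # (block size, within-block latent correlation) pairs; recycled to cover n_snps
    ld_block_spec: list = field(default_factory=lambda: [(6, 0.8)])
    maf_range: tuple = (0.05, 0.5)
    mean_coverage: float = 46.52
    coverage_dispersion: float = 40.0  # NB size parameter; var = mu + mu^2/size
    scenario: str = "mediation"
    b_gm: float = 0.8          # genotype -> methylation, logit units / allele
    b_my: float = 0.3          # methylation -> trait, trait SD / logit unit
    b_gy_direct: float = 0.1   # genotype -> trait direct path (pleiotropy)
    b_yg_rev: float = 0.5      # trait -> methylation, logit units / trait SD
    b_trait_snp: float = 0.45  # per-allele trait effect of trait SNPs (reverse)
    linkage_r2: float = 0.5    # dosage r2 between methylation- and trait-causal SNP
    group_z_threshold: float = 0.8
    logit_noise_sd: float = 0.3
    n_instruments: int = 5
    n_chroms: int = 1
    snp_spacing: int = 10_000  # bp between adjacent SNPs on a chromosome
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        for size, rho in self.ld_block_spec:
            if not (0 <= rho < 1):
                raise ValueError("within-block correlation must lie in [0, 1)")
            if size < 1:
                raise ValueError("block size must be >= 1")
        if self.group_z_threshold <= 0:
            raise ValueError("group_z_threshold must be positive")
        if not (0 <= self.linkage_r2 <= 1):
            raise ValueError("linkage_r2 must lie in [0, 1]")
        if self.mean_coverage <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")

    def blocks(self) -> list:
        """Expand ld_block_spec (recycled) into per-block (size, rho) covering n_snps."""
        out, total, i = [], 0, 0
        if not self.ld_block_spec:
            raise ValueError("ld_block_spec must not be empty")
        while total < self.n_snps:
            size, rho = self.ld_block_spec[i % len(self.ld_block_spec)]
            size = min(size, self.n_snps - total)
            out.append((size, rho))
            total += size
            i += 1
        return out


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulated study produces, plus ground truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix       # methylation cohort (retained extremes)
    methylation: MethylationCounts  # same subjects
    phenotypes: PhenotypeTable
    gwas: SummaryStats              # independent outcome cohort, same SNP panel
    annotations: Optional[np.ndarray] = None  # SNP x track binary
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# LD calibration helpers


def _dosage_corr_from_latent(rho: float, maf1: float, maf2: float) -> float:
    """Pearson correlation of dosages implied by latent correlation ``rho``.

    A haplotype carries the minor allele when its latent Gaussian falls below
    the MAF quantile; the dosage is the sum of two independent haplotypes, so
    the dosage correlation equals the correlation of the allele indicators.
    """
    t1, t2 = stats.norm.ppf(maf1), stats.norm.ppf(maf2)
    if abs(rho) < 1e-12:
        return 0.0
    p11 = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    ).cdf([t1, t2])
    num = p11 - maf1 * maf2
    den = np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    return float(num / den)


def latent_rho_for_dosage_corr(target_r: float, maf1: float, maf2: float) -> float:
    """Invert the threshold model: latent rho giving dosage correlation target_r."""
    if target_r == 0:
        return 0.0
    if not (0 < target_r < 1):
        raise ValueError("target dosage correlation must lie in (0, 1)")
    from scipy.optimize import brentq

    lo_val = _dosage_corr_from_latent(1e-6, maf1, maf2) - target_r
    hi_val = _dosage_corr_from_latent(0.999, maf1, maf2) - target_r
    if lo_val > 0 or hi_val < 0:
        raise ValueError(
            f"dosage correlation {target_r} unattainable at MAFs ({maf1}, {maf2})"
        )
    return float(
        brentq(lambda r: _dosage_corr_from_latent(r, maf1, maf2) - target_r, 1e-6, 0.999)
    )


# ---------------------------------------------------------------------------
# Genotypes


def _block_haplotypes(rng, n_hap: int, mafs: np.ndarray, rho: float) -> np.ndarray:
    """Haplotype allele indicators (n_hap x block size) at latent correlation rho."""
    k = len(mafs)
    common = rng.standard_normal((n_hap, 1))
    indiv = rng.standard_normal((n_hap, k))
    z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * indiv
    return (z < stats.norm.ppf(mafs)[None, :]).astype(np.int8)


def _block_dosages(rng, n: int, mafs: np.ndarray, rho: float,
                   max_retries: int = 20) -> np.ndarray:
    """Dosages for one LD block; monomorphic SNPs are redrawn column-wise."""
    h1 = _block_haplotypes(rng, n, mafs, rho)
    h2 = _block_haplotypes(rng, n, mafs, rho)
    d = (h1 + h2).astype(np.int8)
    for _ in range(max_retries):
        mono = (d.min(axis=0) == d.max(axis=0))
        if not mono.any():
            return d
        # redraw only the offending columns; block LD for them is re-established
        # through fresh correlated latents of the same rho
        sub = _block_haplotypes(rng, n, mafs[mono], rho) + _block_haplotypes(
            rng, n, mafs[mono], rho
        )
        d[:, mono] = sub.astype(np.int8)
    raise RuntimeError(
        "could not obtain polymorphic SNPs after bounded retries; "
        "maf_range is likely too narrow for this sample size"
    )


def _snp_panel(config: SimulationConfig, rng) -> pd.DataFrame:
    """Draw the SNP metadata (positions, alleles, target MAFs) once per study."""
    blocks = config.blocks()
    n = sum(s for s, _ in blocks)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    chroms, positions = [], []
    per_chrom = int(np.ceil(n / config.n_chroms))
    for j in range(n):
        c = j // per_chrom + 1
        chroms.append(str(c))
        positions.append((j % per_chrom + 1) * config.snp_spacing)
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(n)]
    return pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(n)],
            "chrom": chroms,
            "pos": positions,
            "effect_allele": [a for a, _ in pairs],
            "other_allele": [b for _, b in pairs],
            "maf": mafs,
        }
    )


def simulate_genotypes(
    config: SimulationConfig,
    n: int,
    rng=None,
    snps: Optional[pd.DataFrame] = None,
    block_rhos: Optional[list] = None,
) -> GenotypeMatrix:
    """Simulate an n-subject dosage matrix under the configured block LD.

    Haplotypes follow a latent-Gaussian-threshold model: within a block the
    latent variables share correlation rho, and an allele is carried when the
    latent falls below the MAF quantile. Dosage = sum of two independent
    haplotypes. Monomorphic columns are redrawn (bounded retries).
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if snps is None:
        snps = _snp_panel(config, rng)
    blocks = config.blocks()
    rhos = block_rhos if block_rhos is not None else [r for _, r in blocks]
    cols, start = [], 0
    for (size, _), rho in zip(blocks, rhos):
        mafs = snps["maf"].to_numpy()[start:start + size]
        cols.append(_block_dosages(rng, n, mafs, rho))
        start += size
    dosages = np.concatenate(cols, axis=1).astype(float)
    return GenotypeMatrix(dosages, snps.copy())


# ---------------------------------------------------------------------------
# Methylation


def _default_assignments(config: SimulationConfig) -> dict:
    """Instrument map: CpG 0 is causal, driven by the lead SNP of each of the
    first ``n_instruments`` LD blocks at effect ``b_gm``; other CpGs are null."""
    if config.scenario in ("null", "reverse"):
        return {}
    blocks = config.blocks()
    leads, start = [], 0
    for size, _ in blocks:
        leads.append(start)
        start += size
    chosen = leads[: config.n_instruments]
    return {0: [(j, config.b_gm) for j in chosen]}


def _draw_intercepts(n_cpgs: int, rng) -> np.ndarray:
    # spread of baseline methylation levels, roughly beta in (0.18, 0.82)
    return rng.uniform(-1.5, 1.5, size=n_cpgs)


def _center_intercepts(intercepts: np.ndarray, assignments: dict,
                       mafs: np.ndarray) -> np.ndarray:
    """Subtract each assigned CpG's expected genetic logit shift.

    Without centering, the genetic contribution (mean 2*maf*b per SNP) pushes
    causal CpGs toward beta ~ 1, where the logistic saturates and group
    differences vanish on the beta-value scale; a mediator CpG is modelled as
    sitting in the dynamic range of methylation.
    """
    out = intercepts.copy()
    for k, snp_effects in assignments.items():
        out[k] -= sum(b * 2.0 * mafs[j] for j, b in snp_effects)
    return out


def _latent_logits(
    g: GenotypeMatrix,
    assignments: dict,
    intercepts: np.ndarray,
    noise_sd: float,
    rng,
    y: Optional[np.ndarray] = None,
    b_yg_rev: float = 0.0,
    reverse_targets=(0,),
) -> np.ndarray:
    """CpG-by-subject latent methylation propensity on the logit scale.

    Under reverse causation the trait feeds only the CpGs in
    ``reverse_targets``: a trait effect hitting every CpG would be a global
    component indistinguishable from a batch effect (and correctly removed
    by the methylation-PC covariate), which is not the phenomenon modelled.
    """
    lat = np.tile(intercepts[:, None], (1, g.n_subjects))
    for k, snp_effects in assignments.items():
        for j, b in snp_effects:
            lat[k] += b * g.dosages[:, j]
    if y is not None and b_yg_rev != 0.0:
        for k in reverse_targets:
            lat[k] += b_yg_rev * y
    if noise_sd > 0:
        lat += rng.normal(0.0, noise_sd, size=lat.shape)
    return lat


def _counts_from_latent(
    latent: np.ndarray, config: SimulationConfig, rng, cpgs: pd.DataFrame
) -> MethylationCounts:
    mu, size = config.mean_coverage, config.coverage_dispersion
    p_nb = size / (size + mu)
    n = rng.negative_binomial(size, p_nb, size=latent.shape).astype(float)
    p = 1.0 / (1.0 + np.exp(-latent))
    m = rng.binomial(n.astype(int), p).astype(float)
    return MethylationCounts(cpgs, m, n)


def _cpg_table(config: SimulationConfig, snps: pd.DataFrame, assignments: dict, rng) -> pd.DataFrame:
    """Place CpGs: causal CpGs sit in cis of their first instrument; null CpGs
    are scattered uniformly over the SNP span of a random chromosome."""
    chroms = snps["chrom"].unique()
    rows = []
    for k in range(config.n_cpgs):
        if k in assignments and assignments[k]:
            j = assignments[k][0][0]
            chrom = snps["chrom"].iloc[j]
            pos = int(snps["pos"].iloc[j]) + 137  # a cis CpG near its lead mQTL
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            span = snps.loc[snps["chrom"] == chrom, "pos"]
            pos = int(rng.integers(int(span.min()), int(span.max()) + 1))
        rows.append({"id": f"cpg{k:05d}", "chrom": chrom, "pos": pos, "strand": "+"})
    return pd.DataFrame(rows)


def simulate_methylation(
    g: GenotypeMatrix,
    config: SimulationConfig,
    mqtl_assignments: Optional[dict] = None,
    rng=None,
    y: Optional[np.ndarray] = None,
    cpgs: Optional[pd.DataFrame] = None,
    return_latent: bool = False,
):
    """RRBS-style counts for the subjects of ``g``.

    Coverage is negative-binomial (mean/dispersion from the config; zero
    coverage marks a missing observation) and methylated reads are binomial
    around the logistic of the latent propensity. Under the reverse scenario
    the trait value ``y`` enters the logit of the focal CpG (index 0) in
    place of any genetic terms.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if mqtl_assignments is None:
        mqtl_assignments = _default_assignments(config)
    for k, effs in mqtl_assignments.items():
        for j, _ in effs:
            if not (0 <= j < g.n_snps):
                raise ValueError(f"assigned SNP index {j} outside the genotype panel")
    intercepts = _center_intercepts(
        _draw_intercepts(config.n_cpgs, rng), mqtl_assignments,
        g.snps["maf"].to_numpy(),
    )
    if config.scenario == "reverse":
        if y is None:
            raise ValueError("reverse scenario requires the trait values y")
        latent = _latent_logits(g, {}, intercepts, config.logit_noise_sd, rng,
                                y=y, b_yg_rev=config.b_yg_rev)
    else:
        latent = _latent_logits(g, mqtl_assignments, intercepts,
                                config.logit_noise_sd, rng)
    if cpgs is None:
        cpgs = _cpg_table(config, g.snps, mqtl_assignments, rng)
    counts = _counts_from_latent(latent, config, rng, cpgs)
    if return_latent:
        return counts, latent
    return counts


# ---------------------------------------------------------------------------
# Phenotype, extreme-group selection, and the outcome GWAS


def _scenario_effects(config: SimulationConfig) -> dict:
    """Resolve which SNPs carry which direct trait effects, per scenario."""
    assignments = _default_assignments(config)
    blocks = config.blocks()
    leads, start = [], 0
    for size, _ in blocks:
        leads.append(start)
        start += size
    instruments = leads[: config.n_instruments]
    eff = {"meth_causal": [], "trait_direct": {}}
    if config.scenario in ("mediation", "pleiotropy", "linkage"):
        eff["meth_causal"] = [(j, config.b_gm) for j in instruments]
    if config.scenario == "pleiotropy":
        for j in instruments:
            eff["trait_direct"][j] = config.b_gy_direct
    elif config.scenario == "linkage":
        # the trait-causal SNP is the second SNP of each instrument block:
        # a trait locus of its own (same magnitude class as under reverse)
        for b, j in enumerate(instruments):
            size = blocks[b][0]
            partner = j + 1 if size > 1 else j
            eff["trait_direct"][partner] = config.b_trait_snp
    elif config.scenario == "reverse":
        for j in instruments:
            eff["trait_direct"][j] = config.b_trait_snp
    eff["assignments"] = assignments
    return eff


def _trait_values(
    config: SimulationConfig,
    dosages: np.ndarray,
    latent_mediator: Optional[np.ndarray],
    eff: dict,
    rng,
) -> np.ndarray:
    """Continuous trait per subject according to the active scenario."""
    n = dosages.shape[0]
    y = rng.standard_normal(n)
    for j, b in eff["trait_direct"].items():
        y = y + b * dosages[:, j]
    if config.scenario in ("mediation", "pleiotropy") and latent_mediator is not None:
        y = y + config.b_my * latent_mediator
    return y


def _per_snp_regression(y: np.ndarray, dosages: np.ndarray):
    """Vectorized simple linear regression of y on each dosage column."""
    n = len(y)
    g = dosages.astype(float)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    sxy = gc.T @ yc
    beta = sxy / sxx
    rss = (yc @ yc) - beta * sxy
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df=n - 2)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def _simulate_outcome_gwas(
    config: SimulationConfig, snps: pd.DataFrame, eff: dict, seed_seq
) -> SummaryStats:
    """Independent outcome cohort, summarized per SNP; generated block-wise so
    the full genotype matrix is never materialized in double precision."""
    blocks = config.blocks()
    n = config.n_outcome_gwas
    children = seed_seq.spawn(len(blocks) + 2)
    intercept_rng = np.random.default_rng(children[-2])
    noise_rng = np.random.default_rng(children[-1])

    causal_meth = dict(eff["meth_causal"])
    needed = set(causal_meth) | set(eff["trait_direct"])

    # pass 1: regenerate only blocks holding causal SNPs to build y
    start_idx, kept = 0, {}
    for b, (size, rho) in enumerate(blocks):
        idx = range(start_idx, start_idx + size)
        if needed & set(idx):
            rng = np.random.default_rng(children[b])
            d = _block_dosages(rng, n, snps["maf"].to_numpy()[start_idx:start_idx + size], rho)
            for j in needed & set(idx):
                kept[j] = d[:, j - start_idx].astype(float)
        start_idx += size

    latent_mediator = None
    if causal_meth:
        lm = np.zeros(n)
        for j, bgm in causal_meth.items():
            lm += bgm * kept[j]
        # mediator noise mirrors the methylation cohort's latent noise
        lm += intercept_rng.normal(0.0, config.logit_noise_sd, size=n)
        latent_mediator = lm

    y = noise_rng.standard_normal(n)
    for j, b in eff["trait_direct"].items():
        y = y + b * kept[j]
    if config.scenario in ("mediation", "pleiotropy") and latent_mediator is not None:
        y = y + config.b_my * latent_mediator

    # pass 2: regenerate every block (same streams) and regress
    betas = np.empty(len(snps))
    ses = np.empty(len(snps))
    ps = np.empty(len(snps))
    eafs = np.empty(len(snps))
    start_idx = 0
    for b, (size, rho) in enumerate(blocks):
        rng = np.random.default_rng(children[b])
        d = _block_dosages(rng, n, snps["maf"].to_numpy()[start_idx:start_idx + size], rho)
        beta, se, p = _per_snp_regression(y, d)
        sl = slice(start_idx, start_idx + size)
        betas[sl], ses[sl], ps[sl] = beta, se, p
        eafs[sl] = d.mean(axis=0) / 2.0
        start_idx += size

    table = pd.DataFrame(
        {
            "id": snps["id"],
            "effect_allele": snps["effect_allele"],
            "other_allele": snps["other_allele"],
            "beta_zy": betas,
            "se_zy": ses,
            "p": ps,
            "eaf": np.clip(eafs, 1e-6, 1 - 1e-6),
            "n": config.n_outcome_gwas,
        }
    )
    return SummaryStats(table)


def _covariates(n: int, y: np.ndarray, rng) -> pd.DataFrame:
    """Demographic covariates emulating the study cohort: young adult women,
    BMI partially tracking the trait, frequent drinking, moderate smoking."""
    age = rng.normal(31.6, 4.9, size=n).round(1)
    bmi = (25.9 + 1.2 * y + rng.normal(0.0, 4.0, size=n)).clip(15, 60).round(2)
    smoking = (rng.random(n) < 0.36).astype(int)
    drinking = (rng.random(n) < 0.88).astype(int)
    return pd.DataFrame({"age": age, "bmi": bmi, "smoking": smoking, "drinking": drinking})


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generative model and return cohort + GWAS + ground truth.

    The methylation cohort is recruited by generating a larger population
    pool, standardizing the trait to Z-scores against the pool, and retaining
    the first n_subjects/2 subjects of each tail at |Z| >= group_z_threshold.
    The outcome-GWAS cohort is drawn from disjoint RNG streams.
    """
    root = np.random.SeedSequence(config.seed)
    ss_panel, ss_pool, ss_meth, ss_gwas, ss_cov = root.spawn(5)

    panel_rng = np.random.default_rng(ss_panel)
    snps = _snp_panel(config, panel_rng)
    eff = _scenario_effects(config)
    assignments = eff["assignments"]

    blocks = config.blocks()
    block_rhos = [r for _, r in blocks]
    if config.scenario == "linkage" and config.linkage_r2 > 0:
        # calibrate instrument blocks so the dosage correlation between the
        # methylation-causal and trait-causal SNP hits the configured r2
        target_r = float(np.sqrt(config.linkage_r2))
        start = 0
        for b, (size, _) in enumerate(blocks):
            if b < config.n_instruments and size > 1:
                # matched MAFs keep the target dosage correlation attainable
                # under the threshold model (unequal MAFs bound r away from 1)
                m1 = float(snps["maf"].iloc[start])
                snps.loc[start + 1, "maf"] = m1
                block_rhos[b] = latent_rho_for_dosage_corr(target_r, m1, m1)
            start += size

    # --- population pool for extreme-group recruitment
    per_group = config.n_subjects // 2
    if per_group < 2:
        raise ValueError("need at least 2 subjects per extreme group")
    pool_rng = np.random.default_rng(ss_pool)
    tail = stats.norm.sf(config.group_z_threshold)
    pool_n = max(int(np.ceil(per_group / tail * 2.0)), 4 * config.n_subjects)
    for attempt in range(2):
        g_pool = simulate_genotypes(config, pool_n, rng=pool_rng, snps=snps,
                                    block_rhos=block_rhos)
        meth_rng = np.random.default_rng(ss_meth)
        intercepts = _center_intercepts(
            _draw_intercepts(config.n_cpgs, meth_rng), assignments,
            snps["maf"].to_numpy(),
        )
        if config.scenario == "reverse":
            latent_for_y = None
        else:
            latent_for_y = _latent_logits(
                g_pool, assignments, intercepts, config.logit_noise_sd, meth_rng
            )
        mediator = latent_for_y[0] - intercepts[0] if (
            latent_for_y is not None and 0 in assignments
        ) else None
        y_raw = _trait_values(config, g_pool.dosages, mediator, eff, pool_rng)
        z = (y_raw - y_raw.mean()) / y_raw.std()
        hi = np.flatnonzero(z >= config.group_z_threshold)
        lo = np.flatnonzero(z <= -config.group_z_threshold)
        if len(hi) >= per_group and len(lo) >= per_group:
            break
        pool_n *= 2
    else:  # pragma: no cover - second enlargement always suffices
        raise RuntimeError("could not recruit enough extreme-phenotype subjects")
    if len(hi) < 2 or len(lo) < 2:
        raise RuntimeError("fewer than 2 subjects per extreme group")

    keep = np.concatenate([lo[:per_group], hi[:per_group]])
    keep.sort()
    g = g_pool.subset_subjects(keep)
    z_kept = z[keep]
    group = (z_kept >= config.group_z_threshold).astype(int)

    # --- methylation counts for the retained subjects
    if config.scenario == "reverse":
        latent = _latent_logits(g, {}, intercepts, config.logit_noise_sd,
                                meth_rng, y=z_kept, b_yg_rev=config.b_yg_rev)
    else:
        latent = latent_for_y[:, keep]
    cpgs = _cpg_table(config, snps, assignments, meth_rng)
    counts = _counts_from_latent(latent, config, meth_rng, cpgs)

    cov_rng = np.random.default_rng(ss_cov)
    cov = _covariates(len(keep), z_kept, cov_rng)
    pheno = PhenotypeTable(pd.DataFrame({
        "subject": g.subjects,
        "y_continuous": z_kept,
        "group": group,
        **{c: cov[c] for c in cov.columns},
    }))

    gwas = _simulate_outcome_gwas(config, snps, eff, ss_gwas)

    causal_cpg_idx = sorted(assignments)
    if config.scenario == "reverse":
        causal_cpg_idx = [0]  # the trait-responsive CpG
    truth = {
        "scenario": config.scenario,
        "causal_cpgs": [cpgs["id"].iloc[k] for k in causal_cpg_idx],
        "meth_causal_snps": [snps["id"].iloc[j] for j, _ in eff["meth_causal"]],
        "trait_snps": [snps["id"].iloc[j] for j in eff["trait_direct"]],
        "assignments": {
            cpgs["id"].iloc[k]: [(snps["id"].iloc[j], b) for j, b in v]
            for k, v in assignments.items()
        },
        "intercepts": intercepts,
        "config": asdict(config),
    }
    return SimulatedDataset(config, g, counts, pheno, gwas, truth=truth)


# ---------------------------------------------------------------------------
# Annotations


def simulate_annotations(
    g: GenotypeMatrix,
    true_causal: set,
    enrichment_odds: float,
    n_tracks: int,
    seed: int,
    q0: float = 0.1,
) -> np.ndarray:
    """Binary SNP-by-track annotation matrix with configurable causal enrichment.

    Non-causal SNPs are members of each track with probability ``q0``; causal
    SNPs with the probability whose odds are ``enrichment_odds`` times larger.
    """
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")
    rng = np.random.default_rng(seed)
    if n_tracks == 0:
        return np.zeros((g.n_snps, 0), dtype=int)
    odds1 = enrichment_odds * q0 / (1 - q0)
    q1 = odds1 / (1 + odds1)
    causal_mask = g.snps["id"].isin(true_causal).to_numpy()
    probs = np.where(causal_mask, q1, q0)
    return (rng.random((g.n_snps, n_tracks)) < probs[:, None]).astype(int)
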