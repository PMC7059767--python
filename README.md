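# methmediate

Causal-inference toolkit for asking whether CpG methylation sites *mediate*
genetic influences on a complex trait, from bisulfite-sequencing count data
and GWAS summary statistics.

## The science

If a genetic variant changes methylation at a CpG site and that
methylation change alters the trait, the CpG is a *mediator* — a
mechanistic link and a potential intervention point. The hard part is that
a methylation-trait association can arise four ways:

1. **mediation** — genotype → methylation → trait (the interesting case);
2. **linkage** — two *different* causal variants in linkage disequilibrium
   (LD), one driving methylation and one the trait;
3. **horizontal pleiotropy** — one variant independently affecting both;
4. **reverse causation** — the trait (or its genetic drivers) altering
   methylation.

`methmediate` implements the summary-data causal-inference stack that
separates these explanations:

- **count-based EWAS**: binomial logistic regression of methylated/total
  read counts on the phenotype group, with coverage filters and
  Bonferroni + effect-size selection of differentially methylated CpGs
  (DMCs);
- **mQTL mapping**: cis/trans scan with SNP QC (MAF, call rate, exact
  Hardy-Weinberg) and per-class Bonferroni thresholds;
- **two-sample Mendelian randomization (MR)**: allele harmonization,
  LD pruning, MR-Steiger orientation gates, and Wald-ratio / IVW /
  MR-Egger / weighted-median / maximum-likelihood estimators with
  Benjamini-Hochberg mediator selection;
- **HEIDI colocalization**: tests whether one shared causal variant
  explains the locus, with an exact weighted-chi-square p-value (Imhof);
- **reverse MR**: one-sample 2SLS of methylation on the genetically
  predicted trait with weak-instrument diagnostics;
- **annotation-aware fine-mapping**: exact enumeration of causal
  configurations with annotation priors fitted by EM, yielding per-SNP
  posterior inclusion probabilities (PIPs);
- **permutation enrichment** of DMCs in annotation tracks;
- a **synthetic RRBS cohort generator** with planted mediation, linkage,
  pleiotropy, reverse-causation and null scenarios, used to validate the
  whole stack end to end.

Estimation follows a statsmodels-style pattern throughout: construct a
model object, call `.fit()`, get a results object with a `.summary()`.

## Worked example

Simulate a 150-subject extreme-group methylation cohort plus a 50,000
subject outcome GWAS under the mediation scenario, and run the stages by
hand:

```python
import warnings; warnings.filterwarnings("ignore")
from methmediate import (SimulationConfig, simulate_dataset, EWASModel,
                         MQTLScan, MendelianRandomization)
from methmediate.mqtl import ld_matrix

cfg = SimulationConfig(scenario="mediation", seed=7)
ds = simulate_dataset(cfg)

ewas = EWASModel(ds.methylation, ds.phenotypes.group,
                 covariates=ds.phenotypes.covariate_matrix()).fit()
print(ewas.summary())
```

```
Differential methylation (binomial logistic regression)
  CpGs tested (Bonferroni family): 50
  CpGs dropped by coverage filter: 0
  non-converged fits (excluded):   0
  DMCs at |diff| > 0.05:           1
  DMCs at |diff| >= 0.10:          1
  meth_diff convention: percent (high minus low group)
```

The one DMC is the planted mediator CpG:

```python
print(ewas.dmcs()[["cpg", "p", "meth_diff"]].to_string(index=False))
```

```
     cpg            p  meth_diff
cpg00000 2.036168e-20  15.165112
```

Map its mQTLs and run two-sample MR against the outcome GWAS:

```python
scan = MQTLScan(ds.genotypes, ds.methylation, cpg_ids=["cpg00000"]).fit()
sig = scan.significant
mr = MendelianRandomization(
    sig[["snp", "b_zx", "se_zx", "p"]], ds.gwas,
    ld=ld_matrix(ds.genotypes, list(sig["snp"])),
    exposure_alleles=ds.genotypes.snps[["id", "effect_allele", "other_allele"]],
    positions=dict(zip(ds.genotypes.snps["id"], ds.genotypes.snps["pos"])),
    cpg="cpg00000")
print(mr.summary())
```

```
Two-sample MR, DMC cpg00000 (5 instruments after pruning)
  ivw_fe           b_xy=+0.2730 se=0.0194 p=8.76e-45
  ivw_mre          b_xy=+0.2730 se=0.0291 p=6.18e-21
  egger            b_xy=-0.0170 se=0.0178 p=0.412
  weighted_median  b_xy=+0.2859 se=0.0267 p=1.08e-26
  max_likelihood   b_xy=+0.2869 se=0.0216 p=2.04e-40
```

The planted methylation→trait effect is 0.3; IVW, weighted median and
maximum likelihood recover it. (MR-Egger is uninformative here by design:
the planted instruments share one exposure effect size, and Egger's slope
is unidentified without spread in instrument strength — its intercept
soaks up the signal. A known property, not a failure.)

### The full pipeline from the command line

```bash
methmediate run --seed 1002 --scenario mediation --out-dir out/
```

```
     cpg method  n_snp     b_mr    se_mr         p_mr         q_mr   b_egger  se_egger  p_egger  top_snp  p_heidi  n_snp_heidi top_causal_mqtl  pip  meth_diff        p_dmc  p_reverse              verdict
cpg00000 ivw_fe      4 0.320951 0.026278 2.630714e-34 2.630714e-34 -0.018062  0.015208 0.356886 snp00012  0.40486            3        snp00012  1.0  16.385116 1.731923e-48        NaN mediation-consistent
```

One CpG reaches the mediator report: the MR effect is FDR-significant,
HEIDI does not reject the shared-causal-variant null (p = 0.40), the
reverse-direction test never fires, fine-mapping puts PIP 1.0 on the lead
mQTL SNP, and the verdict is **mediation-consistent**. All stage artifacts
(`ewas.tsv`, `mr.tsv`, `heidi.tsv`, `finemap.tsv`, `mediator_report.tsv`,
`verdict_summary.json`, …) are written to `out/`. Per-stage subcommands
(`methmediate simulate`, `methmediate ewas`, …) run one step at a time;
`--config cfg.yaml` overrides any pipeline parameter.

## Verdict logic

For each FDR-selected mediator CpG the pipeline combines four tests, in
precedence order: `linkage` (MR significant but HEIDI rejects),
`reverse-causal` (reverse 2SLS significant), `mediation-consistent`
(MR significant, both challenges silent), else `inconclusive`. HEIDI
precedes the reverse test because a HEIDI rejection positively identifies
two distinct causal variants, which also explains a residual reverse-2SLS
signal through LD. See `docs/methods.md` for the model specifications,
validation design and measured operating characteristics (86 % mediation
detection, 0 % null false positives, 82 % linkage detection over 100
replicates per scenario).

## Tests and reproduction

```bash
python -m pytest            # full suite, ~10 min (unit tests alone: ~10 s)
```

`tests/test_acceptance.py` holds the six end-to-end properties (threshold
reproduction, scenario discrimination, estimator calibration, brute-force
oracle equivalence, parameter recovery, determinism/runtime) on frozen
seeds.

The headline numbers can be regenerated under any seed:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes every quantity as `{"name": {"value": ..., "n": ...}}`:
detection/false-positive rates (100 pipeline replicates per scenario),
type-I error (1000 replicates), IVW interval coverage (200 replicates),
fine-mapping and HEIDI oracle discrepancies, EM annotation-odds recovery,
and the full-scale runtime and byte-reproducibility check. Roughly 10
minutes on one CPU; all randomness derives from `--seed`.
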