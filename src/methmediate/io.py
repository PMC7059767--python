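"""Interchange formats: VCF, dosage TSV, Bismark coverage, summary-stats TSV,
BED, LD matrix, and phenotype tables.

Coordinate conventions: VCF and Bismark coverage files are 1-based (coverage
intervals inclusive); BED is 0-based half-open. All writers round-trip
losslessly through their paired readers.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from methmediate.datatypes import (
    GenotypeMatrix,
    LDMatrix,
    MethylationCounts,
    PhenotypeTable,
    SummaryStats,
)

__all__ = [
    "write_vcf", "read_vcf",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_bismark_coverage", "read_bismark_coverage",
    "write_phenotypes", "read_phenotypes",
    "write_summary_stats", "read_summary_stats",
    "write_bed", "read_bed",
    "write_ld_matrix", "read_ld_matrix",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write hard-called genotypes as a minimal VCF with GT fields.

    REF is the other allele and ALT the effect (dosage-counted) allele, so a
    dosage of 2 maps to GT 1/1.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.subjects) + "\n")
        for j in range(g.n_snps):
            s = g.snps.iloc[j]
            calls = []
            for i in range(g.n_subjects):
                d = g.dosages[i, j]
                calls.append("./." if np.isnan(d) else _GT[int(d)])
            fh.write(
                f"{s['chrom']}\t{int(s['pos'])}\t{s['id']}\t{s['other_allele']}\t"
                f"{s['effect_allele']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _read_vcf_text(path: str) -> GenotypeMatrix:
    subjects, rows, dosages = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                subjects = line.split("\t")[9:]
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: malformed VCF record")
            chrom, pos, vid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            calls = []
            for c in f[9:]:
                gt = c.split(":")[0].replace("|", "/")
                if gt in (".", "./."):
                    calls.append(np.nan)
                else:
                    calls.append(float(sum(int(a) for a in gt.split("/"))))
            rows.append({"id": vid, "chrom": chrom, "pos": pos,
                         "effect_allele": alt, "other_allele": ref})
            dosages.append(calls)
    d = np.asarray(dosages, dtype=float).T
    snps = pd.DataFrame(rows)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    snps["maf"] = np.minimum(p, 1 - p)
    return GenotypeMatrix(d, snps, subjects)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (dosage of the ALT allele).

    Uses cyvcf2 when available, with a plain-text fallback parser.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(path)
    subjects = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        gts = var.genotype.array()
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        dos = alleles.sum(axis=1)
        rows.append({
            "id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": str(var.CHROM),
            "pos": int(var.POS),
            "effect_allele": var.ALT[0] if var.ALT else ".",
            "other_allele": var.REF,
        })
        dosages.append(dos)
    d = np.asarray(dosages, dtype=float).T
    snps = pd.DataFrame(rows)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    snps["maf"] = np.minimum(p, 1 - p)
    return GenotypeMatrix(d, snps, subjects)


def write_dosage_tsv(g: GenotypeMatrix, path: str) -> None:
    """Plain dosage matrix: SNP metadata columns then one column per subject."""
    meta = g.snps[["id", "chrom", "pos", "effect_allele", "other_allele"]]
    dose = pd.DataFrame(g.dosages.T, columns=g.subjects, index=meta.index)
    df = pd.concat([meta, dose], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta_cols = ["id", "chrom", "pos", "effect_allele", "other_allele"]
    subjects = [c for c in df.columns if c not in meta_cols]
    d = df[subjects].to_numpy(dtype=float).T
    snps = df[meta_cols].copy()
    snps["chrom"] = snps["chrom"].astype(str)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    snps["maf"] = np.minimum(p, 1 - p)
    return GenotypeMatrix(d, snps, subjects)


def write_bismark_coverage(counts: MethylationCounts, out_dir: str,
                           prefix: str = "") -> list:
    """One Bismark-style coverage file per subject.

    Columns: chrom, start, end, methylation%, count-methylated,
    count-unmethylated; positions 1-based inclusive (start == end for a CpG).
    CpGs without coverage for a subject are omitted from that subject's file.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, subj in enumerate(counts.subjects):
        path = os.path.join(out_dir, f"{prefix}{subj}.cov")
        with open(path, "w") as fh:
            for k in range(counts.n_cpgs):
                n = counts.n[k, i]
                if not np.isfinite(n) or n <= 0:
                    continue
                m = counts.m[k, i]
                pct = 100.0 * m / n
                row = counts.cpgs.iloc[k]
                fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{int(row['pos'])}\t"
                         f"{pct:.6g}\t{int(m)}\t{int(n - m)}\n")
        paths.append(path)
    return paths


def read_bismark_coverage(paths: Iterable, subjects=None) -> MethylationCounts:
    """Assemble per-subject coverage files into a MethylationCounts matrix."""
    paths = list(paths)
    if subjects is None:
        subjects = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    per_subject = []
    keys = {}
    for path in paths:
        rec = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                f = line.rstrip("\n").split("\t")
                if len(f) != 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(f)}")
                try:
                    chrom, start = f[0], int(f[1])
                    cm, cu = int(f[4]), int(f[5])
                except ValueError as err:
                    raise ValueError(f"{path}:{lineno}: malformed coverage line") from err
                key = (chrom, start)
                keys.setdefault(key, len(keys))
                rec[key] = (cm, cm + cu)
        per_subject.append(rec)
    ordered = sorted(keys, key=lambda k: (k[0], k[1]))
    m = np.zeros((len(ordered), len(paths)))
    n = np.zeros((len(ordered), len(paths)))
    for i, rec in enumerate(per_subject):
        for k, key in enumerate(ordered):
            if key in rec:
                m[k, i], n[k, i] = rec[key]
    cpgs = pd.DataFrame({
        "id": [f"{c}:{p}" for c, p in ordered],
        "chrom": [c for c, _ in ordered],
        "pos": [p for _, p in ordered],
        "strand": "+",
    })
    return MethylationCounts(cpgs, m, n, list(subjects))


def write_phenotypes(pheno: PhenotypeTable, path: str) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


_SS_HEADER = ["SNP", "A1", "A2", "BETA", "SE", "P", "EAF", "N"]


def write_summary_stats(ss: SummaryStats, path: str) -> None:
    """Headered TSV: SNP, A1 (effect allele), A2, BETA, SE, P, EAF, N."""
    out = ss.table.rename(columns={
        "id": "SNP", "effect_allele": "A1", "other_allele": "A2",
        "beta_zy": "BETA", "se_zy": "SE", "p": "P", "eaf": "EAF", "n": "N",
    })[_SS_HEADER]
    out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str) -> SummaryStats:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SS_HEADER:
            raise ValueError(f"{path}:1: expected header {_SS_HEADER}, got {header}")
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_SS_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_SS_HEADER)} columns")
            try:
                rows.append({
                    "id": f[0], "effect_allele": f[1], "other_allele": f[2],
                    "beta_zy": float(f[3]), "se_zy": float(f[4]),
                    "p": float(f[5]), "eaf": float(f[6]), "n": float(f[7]),
                })
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from err
            if not np.isfinite(rows[-1]["se_zy"]) or rows[-1]["se_zy"] <= 0:
                raise ValueError(f"{path}:{lineno}: SE must be positive and finite")
    return SummaryStats(pd.DataFrame(rows))


def write_bed(intervals, path: str, names=None) -> None:
    """Write (chrom, start, end) intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            line = f"{chrom}\t{int(start)}\t{int(end)}"
            if names is not None:
                line += f"\t{names[i]}"
            fh.write(line + "\n")


def read_bed(path: str) -> list:
    """Read BED intervals as (chrom, start, end) tuples (0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from err
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            out.append((f[0], start, end))
    return out


def write_ld_matrix(ld: LDMatrix, path: str) -> None:
    df = pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids)
    df.index.name = f"n={ld.source_n}"
    df.to_csv(path, sep="\t")


def read_ld_matrix(path: str) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    source_n = 0
    if df.index.name and df.index.name.startswith("n="):
        source_n = int(df.index.name[2:])
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float), source_n)
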