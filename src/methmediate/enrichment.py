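"""Permutation enrichment of DMCs in genomic annotation tracks.

For each annotation track the observed proportion of DMCs overlapping the
track is contrasted with the overlap of random CpG sets of the same size
drawn (without replacement) from the full tested background. Fold enrichment
is observed/expected and the empirical p uses the add-one convention, so
p >= 1/(n_perm + 1) and is never exactly zero. Enrichment is one-sided;
depletion shows up as fold < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["overlap_track", "permute_enrichment", "EnrichmentResult"]


@dataclass
class EnrichmentResult:
    track: str
    observed_prop: float
    expected_prop: float
    fold: float
    p_emp: float
    n_perm: int
    n_dmcs: int


def overlap_track(cpgs: pd.DataFrame, intervals) -> np.ndarray:
    """Binary overlap of each CpG with a set of BED-style intervals.

    ``cpgs`` has columns chrom and pos (1-based); ``intervals`` is an
    iterable of (chrom, start, end) in BED 0-based half-open convention, so a
    1-based position p overlaps [start, end) iff start < p <= end.
    """
    by_chrom = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = (np.array([s for s, _ in out]),
                         np.array([e for _, e in out]))
    hits = np.zeros(len(cpgs), dtype=int)
    for i, (chrom, pos) in enumerate(zip(cpgs["chrom"], cpgs["pos"])):
        if str(chrom) not in merged:
            continue
        starts, ends = merged[str(chrom)]
        # 1-based pos p lies in 0-based half-open [s, e) iff s <= p-1 < e
        j = np.searchsorted(starts, pos - 1, side="right") - 1
        if j >= 0 and pos - 1 < ends[j]:
            hits[i] = 1
    return hits


def permute_enrichment(
    dmc_ids,
    background: pd.DataFrame,
    intervals,
    track_name: str = "",
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test of DMC enrichment in one annotation track.

    ``background`` is the table of all tested CpGs (columns id, chrom, pos);
    ``dmc_ids`` must be a subset of its ids. Draws ``n_perm`` random subsets
    of size len(dmc_ids) without replacement and reports fold enrichment
    observed/expected with the add-one empirical p.
    """
    dmc_ids = list(dmc_ids)
    ids = background["id"].to_numpy()
    is_dmc = np.isin(ids, dmc_ids)
    if is_dmc.sum() != len(set(dmc_ids)):
        raise ValueError("dmcs must be a subset of the background CpGs")
    n_dmc = int(is_dmc.sum())
    if n_dmc == 0 or len(background) < n_dmc:
        raise ValueError("need 0 < |dmcs| <= |background|")
    overlap = overlap_track(background, intervals)
    observed = float(overlap[is_dmc].mean())
    rng = np.random.default_rng(seed)
    props = np.empty(n_perm)
    n_bg = len(background)
    for b in range(n_perm):
        pick = rng.choice(n_bg, size=n_dmc, replace=False)
        props[b] = overlap[pick].mean()
    expected = float(props.mean())
    p_emp = float((1 + (props >= observed).sum()) / (n_perm + 1))
    if expected > 0:
        fold = observed / expected
    else:
        import warnings

        warnings.warn(f"track {track_name}: expected overlap 0, fold undefined",
                      stacklevel=2)
        fold = float("nan")
    return EnrichmentResult(track_name, observed, expected, fold, p_emp,
                            n_perm, n_dmc)
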