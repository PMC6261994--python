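"""Colocalization of ancestry-specific loci with positively-selected genomic
regions and exact binomial enrichment testing."""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenomicRegion


def overlap_loci_regions(
    sentinels: pd.DataFrame, regions: list[GenomicRegion]
) -> tuple[pd.Series, int]:
    """Flag sentinel SNPs falling inside any selected region.

    ``sentinels`` needs columns CHR and POS (1-based); regions are 0-based
    half-open, so a sentinel at 1-based position p hits [start, end) iff
    start <= p-1 < end.  Returns (hit flags aligned to sentinels, k).
    """
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(str(r.chrom), []).append(r)
    hits = []
    for row in sentinels.itertuples(index=False):
        pos0 = int(row.POS) - 1
        hits.append(
            any(r.contains(pos0) for r in by_chrom.get(str(row.CHR), []))
        )
    flags = pd.Series(hits, index=sentinels.index, name="SELECTED")
    return flags, int(flags.sum())


def merge_regions(regions: list[GenomicRegion]) -> list[GenomicRegion]:
    """Merge overlapping/adjacent intervals per chromosome (idempotent)."""
    merged: list[GenomicRegion] = []
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(str(r.chrom), []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: r.start)
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end:
                cur_end = max(cur_end, r.end)
            else:
                merged.append(GenomicRegion(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(GenomicRegion(chrom, cur_start, cur_end))
    return merged


def background_probability(
    regions: list[GenomicRegion], genome_length: float
) -> float:
    """Fraction of the genome covered by the (merged) regions."""
    if not regions:
        warnings.warn("empty region list: background probability is 0")
        return 0.0
    total = sum(r.length for r in merge_regions(regions))
    if total >= genome_length:
        raise ValueError("merged region length exceeds the genome length")
    return total / genome_length


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial P(X >= k | n, p0) by direct summation."""
    if k > n:
        raise ValueError("k cannot exceed n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if k <= 0:
        return 1.0
    ks = np.arange(k, n + 1)
    return float(np.sum(sps.binom.pmf(ks, n, p0)))


@dataclass
class EnrichmentResult:
    """Selection-region enrichment at ancestry-specific loci."""

    k: int
    n: int
    p0: float
    p_binomial: float


def enrichment_test(
    sentinels: pd.DataFrame,
    regions: list[GenomicRegion],
    p0: float | None = None,
    genome_length: float = 3.0e9,
) -> EnrichmentResult:
    """Colocalize sentinels with selected regions and test for enrichment.

    ``p0`` is the per-locus background hit probability.  It defaults to the
    genome fraction covered by the merged regions, but should be supplied
    explicitly when reproducing published numbers (the enrichment is
    sensitive to it).
    """
    _, k = overlap_loci_regions(sentinels, regions)
    n = len(sentinels)
    if p0 is None:
        p0 = background_probability(regions, genome_length)
    p = binomial_enrichment(k, n, p0) if 0.0 < p0 < 1.0 else 1.0
    return EnrichmentResult(k=k, n=n, p0=p0, p_binomial=p)
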