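"""Heritability-based GWAS power and cross-ancestry locus-overlap simulation.

Given heritability parameters (h2, causal fraction, cross-population effect
correlation, population-specific causal fraction), the simulator repeatedly
samples true standardized effect sizes, draws LD-free observed Z statistics
Z ~ Normal(sqrt(N) b, 1) per SNP, merges genome-wide significant SNPs into
loci by the 500-kb chaining rule, and counts significant loci per population
and their interethnic overlap over a grid of sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .loci import MAX_GAP


@dataclass
class PowerConfig:
    """Study conditions for the power/overlap simulation."""

    h2: tuple[float, float] = (0.107, 0.086)
    pi: float = 0.01
    rho_g: float = 0.9
    pop_specific_frac: float = 0.0
    m_snps: int = 100_000
    genome_length: float = 3.0e9
    n_chrom: int = 22
    n_grid: tuple[int, ...] = (100_000, 200_000, 500_000)
    threshold: float = 5e-8
    merge_distance: int = MAX_GAP
    n_trials: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


def sample_true_effects(
    config: PowerConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-population standardized effect vectors and positions.

    Causal indicators are Bernoulli(pi); shared causal effects come from a
    bivariate normal with correlation rho_g and per-population variance
    h2 / (m pi); a ``pop_specific_frac`` fraction of causal SNPs carries an
    effect in exactly one population.  Positions are uniform over equal-length
    chromosomes.  Returns (b1, b2, chrom, pos).
    """
    m = config.m_snps
    causal = rng.uniform(size=m) < config.pi
    n_causal = int(causal.sum())
    b1 = np.zeros(m)
    b2 = np.zeros(m)
    if n_causal:
        sd = np.sqrt(np.asarray(config.h2) / (m * config.pi))
        z1 = rng.standard_normal(n_causal)
        z2 = config.rho_g * z1 + np.sqrt(1 - config.rho_g**2) * rng.standard_normal(
            n_causal
        )
        b1[causal] = sd[0] * z1
        b2[causal] = sd[1] * z2
        n_spec = int(round(config.pop_specific_frac * n_causal))
        if n_spec:
            spec = rng.permutation(np.flatnonzero(causal))[:n_spec]
            b1[spec[: n_spec // 2]] = 0.0
            b2[spec[n_spec // 2:]] = 0.0
    chrom_len = config.genome_length / config.n_chrom
    chrom = rng.integers(0, config.n_chrom, size=m)
    pos = rng.uniform(0, chrom_len, size=m)
    order = np.lexsort((pos, chrom))
    return b1[order], b2[order], chrom[order], pos[order]


def _merge_significant(chrom: np.ndarray, pos: np.ndarray, merge_distance: float):
    """Locus ids for significant SNPs sorted by (chrom, pos)."""
    if chrom.size == 0:
        return np.empty(0, dtype=int)
    new = np.ones(chrom.size, dtype=bool)
    new[1:] = (chrom[1:] != chrom[:-1]) | (np.diff(pos) > merge_distance)
    return np.cumsum(new) - 1


def significant_loci_count(
    b: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    n: int,
    rng: np.random.Generator,
    threshold: float = 5e-8,
    merge_distance: int = MAX_GAP,
) -> tuple[int, np.ndarray]:
    """Observed significant-locus count for one trial at sample size n.

    Z ~ Normal(sqrt(n) b, 1) independently per SNP; SNPs with two-sided
    P < threshold are merged into loci by <= merge_distance chaining.
    Returns (locus count, indices of significant SNPs).
    """
    z_crit = sps.norm.isf(threshold / 2.0)
    z = np.sqrt(n) * b + rng.standard_normal(b.size)
    sig = np.flatnonzero(np.abs(z) > z_crit)
    locus_ids = _merge_significant(chrom[sig], pos[sig], merge_distance)
    count = int(locus_ids.max() + 1) if sig.size else 0
    return count, sig


def _count_overlap(
    chrom1, pos1, chrom2, pos2, merge_distance: float
) -> tuple[int, int]:
    """Count loci of population 1 with some significant SNP of population 2
    within merge_distance; returns (n_loci_1, n_overlapping_1)."""
    ids1 = _merge_significant(chrom1, pos1, merge_distance)
    n1 = int(ids1.max() + 1) if ids1.size else 0
    overlap = 0
    for locus in range(n1):
        sel = ids1 == locus
        c = chrom1[sel][0]
        near = (chrom2 == c) & (
            (pos2 >= pos1[sel].min() - merge_distance)
            & (pos2 <= pos1[sel].max() + merge_distance)
        )
        if near.any():
            overlap += 1
    return n1, overlap


@dataclass
class PowerResult:
    """Mean locus counts and interethnic overlap per sample size."""

    table: pd.DataFrame  # N, COUNT_1, SE_1, COUNT_2, SE_2, OVERLAP,
    #                      NONOVERLAP_1, NONOVERLAP_2
    config: PowerConfig = field(repr=False, default=None)


def overlap_simulation(config: PowerConfig) -> PowerResult:
    """Monte-Carlo expected significant-locus counts and overlap.

    Per trial and sample size, loci are computed per population; a locus
    overlaps when any of its significant SNPs lies within the merge distance
    of a significant SNP of the other population.  Counts are averaged over
    ``n_trials`` with Monte-Carlo SEs; the nonoverlap proportion per
    population is nonoverlap / (overlap + nonoverlap).
    """
    rng = np.random.default_rng(config.seed)
    grid = list(config.n_grid)
    counts = {n: ([], [], [], []) for n in grid}  # c1, c2, ov1, ov2
    for _ in range(config.n_trials):
        b1, b2, chrom, pos = sample_true_effects(config, rng)
        for n in grid:
            _, sig1 = significant_loci_count(
                b1, chrom, pos, n, rng, config.threshold, config.merge_distance
            )
            _, sig2 = significant_loci_count(
                b2, chrom, pos, n, rng, config.threshold, config.merge_distance
            )
            c1, ov1 = _count_overlap(
                chrom[sig1], pos[sig1], chrom[sig2], pos[sig2], config.merge_distance
            )
            c2, ov2 = _count_overlap(
                chrom[sig2], pos[sig2], chrom[sig1], pos[sig1], config.merge_distance
            )
            counts[n][0].append(c1)
            counts[n][1].append(c2)
            counts[n][2].append(ov1)
            counts[n][3].append(ov2)

    rows = []
    for n in grid:
        c1, c2, ov1, ov2 = (np.asarray(v, dtype=float) for v in counts[n])
        t = config.n_trials
        total1, total2 = c1.sum(), c2.sum()
        rows.append(
            {
                "N": n,
                "COUNT_1": c1.mean(),
                "SE_1": c1.std(ddof=1) / np.sqrt(t) if t > 1 else np.nan,
                "COUNT_2": c2.mean(),
                "SE_2": c2.std(ddof=1) / np.sqrt(t) if t > 1 else np.nan,
                "OVERLAP_1": ov1.mean(),
                "OVERLAP_2": ov2.mean(),
                "NONOVERLAP_1": (total1 - ov1.sum()) / total1 if total1 else np.nan,
                "NONOVERLAP_2": (total2 - ov2.sum()) / total2 if total2 else np.nan,
            }
        )
    return PowerResult(table=pd.DataFrame(rows), config=config)
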