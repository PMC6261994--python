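"""Locus construction, sentinel selection, novelty nomination and
cross-population locus classification.

A locus is the transitive chaining of genome-wide significant SNPs at most
500 kb apart on the same chromosome.  Sentinels are minimum-P members (ties
broken by position, then id).  Loci are classified by the sentinel's MAF in
the two populations: group 1 (MAF >= 0.01 in both), group 2a (< 0.01 in one,
>= 0.05 in the other), group 2b (< 0.01 in one, 0.01 <= MAF < 0.05 in the
other), excluded when rare in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

#: default locus chaining distance, base pairs ("at most 500 kb" inclusive)
MAX_GAP = 500_000


class LocusGroup(str, Enum):
    GROUP1 = "group1"
    GROUP2A = "group2a"
    GROUP2B = "group2b"
    EXCLUDED = "excluded"
    UNASSIGNED = "unassigned"


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    members: list[str]
    sentinel: str = ""
    sentinel_trait: str = ""
    sentinel_p: float = np.nan
    group_label: LocusGroup = LocusGroup.UNASSIGNED
    maf_pair: tuple[float, float] | None = None
    trait_sentinels: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def cluster_loci(snps: pd.DataFrame, max_gap: int = MAX_GAP) -> list[Locus]:
    """Partition SNPs into loci by transitive <= max_gap chaining.

    ``snps`` needs columns CHR, POS, SNP.  Two SNPs belong to the same locus
    iff they are linked by a chain of same-chromosome steps each at most
    ``max_gap`` apart ("at most" inclusive).
    """
    loci: list[Locus] = []
    if snps.empty:
        return loci
    frame = snps.sort_values(["CHR", "POS"], kind="mergesort")
    for chrom, grp in frame.groupby("CHR", sort=True):
        pos = grp["POS"].to_numpy()
        ids = grp["SNP"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for segment in np.split(np.arange(len(pos)), breaks):
            loci.append(
                Locus(
                    chrom=str(chrom),
                    start=int(pos[segment[0]]),
                    end=int(pos[segment[-1]]),
                    members=list(ids[segment]),
                )
            )
    return loci


def select_sentinel(locus: Locus, p_values: pd.DataFrame) -> Locus:
    """Pick per-trait and cross-trait sentinels by minimum P.

    ``p_values`` has columns SNP, TRAIT, P (and optionally POS).  Ties are
    broken by lower P, then smaller position, then lexicographic id.
    """
    t = p_values[p_values["SNP"].isin(locus.members)].copy()
    if t.empty:
        raise ValueError("no P values for locus members")
    if "POS" not in t.columns:
        order = {s: i for i, s in enumerate(locus.members)}
        t["POS"] = t["SNP"].map(order)
    t = t.sort_values(["P", "POS", "SNP"], kind="mergesort")
    locus.trait_sentinels = {
        trait: grp.iloc[0]["SNP"] for trait, grp in t.groupby("TRAIT")
    }
    best = t.iloc[0]
    locus.sentinel = str(best["SNP"])
    locus.sentinel_trait = str(best["TRAIT"])
    locus.sentinel_p = float(best["P"])
    return locus


def nominate_novel(
    sentinels: pd.DataFrame,
    known_snps: pd.DataFrame,
    ld_lookup=None,
    max_distance: int = MAX_GAP,
    r2_threshold: float = 0.1,
) -> pd.DataFrame:
    """Flag sentinel SNPs as novel relative to known trait-associated SNPs.

    A sentinel is NOT novel if any known SNP on its chromosome is within
    ``max_distance`` or has LD r^2 >= ``r2_threshold`` with it; otherwise it
    is novel.  ``ld_lookup(snp_a, snp_b) -> r2 or None`` supplies LD in the
    designated reference population; None (SNP absent from the panel) leaves
    the pair unreviewable and flags the sentinel for manual review.
    """
    out = sentinels.copy()
    novel = []
    review = []
    for row in sentinels.itertuples(index=False):
        near = known_snps[
            (known_snps["CHR"] == row.CHR)
            & ((known_snps["POS"] - row.POS).abs() <= max_distance)
        ]
        is_novel = True
        needs_review = False
        if len(near):
            is_novel = False
        elif ld_lookup is not None:
            for ksnp in known_snps.loc[known_snps["CHR"] == row.CHR, "SNP"]:
                r2 = ld_lookup(row.SNP, ksnp)
                if r2 is None:
                    needs_review = True
                elif r2 >= r2_threshold:
                    is_novel = False
                    break
        novel.append(is_novel)
        review.append(needs_review)
    out["NOVEL"] = novel
    out["NEEDS_REVIEW"] = review
    return out


def classify_groups(maf1: float, maf2: float) -> LocusGroup:
    """Cross-population MAF classification of a locus (by its sentinel)."""
    if maf1 is None or maf2 is None or np.isnan(maf1) or np.isnan(maf2):
        return LocusGroup.EXCLUDED
    lo, hi = sorted((maf1, maf2))
    if lo >= 0.01:
        return LocusGroup.GROUP1
    if hi >= 0.05:
        return LocusGroup.GROUP2A
    if hi >= 0.01:
        return LocusGroup.GROUP2B
    return LocusGroup.EXCLUDED


def classify_locus(locus: Locus) -> Locus:
    if locus.maf_pair is None:
        locus.group_label = LocusGroup.EXCLUDED
    else:
        locus.group_label = classify_groups(*locus.maf_pair)
    return locus


class AncestryFlag(str, Enum):
    SPECIFIC = "specific"
    NOT_SPECIFIC = "not_specific"
    INELIGIBLE = "ineligible"


def flag_ancestry_specific(
    sentinel_pos: int,
    sentinel_chrom: str,
    sentinel_p: float,
    other_maf: float,
    other_stats: pd.DataFrame,
    window: int = MAX_GAP,
    gw_threshold: float = 5e-8,
) -> tuple[AncestryFlag, dict]:
    """Ancestry-specificity of a genome-wide significant sentinel.

    Requires the sentinel significant in the index population
    (P < ``gw_threshold``).  In the other population the variant must be rare
    (MAF < 0.05) or monomorphic, and no SNP within +-window may pass the
    window-wise Bonferroni threshold 0.05/m (m = number of window SNPs).
    An empty window counts as specific (no detectable signal), with a note.
    """
    if not sentinel_p < gw_threshold:
        raise ValueError("sentinel must be genome-wide significant in index pop")
    detail: dict = {}
    if other_maf is not None and not np.isnan(other_maf) and other_maf >= 0.05:
        return AncestryFlag.INELIGIBLE, detail
    win = other_stats[
        (other_stats["CHR"] == sentinel_chrom)
        & ((other_stats["POS"] - sentinel_pos).abs() <= window)
    ]
    m = len(win)
    detail["m_window"] = m
    if m == 0:
        detail["warning"] = "empty window in other population"
        return AncestryFlag.SPECIFIC, detail
    min_p = float(win["P"].min())
    threshold = 0.05 / m
    detail["min_p"] = min_p
    detail["threshold"] = threshold
    if min_p > threshold:
        return AncestryFlag.SPECIFIC, detail
    return AncestryFlag.NOT_SPECIFIC, detail
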