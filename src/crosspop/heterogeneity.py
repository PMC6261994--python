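"""Interethnic heterogeneity of genetic impact and the haplo-SNP procedure.

The genetic (allelic) impact of a SNP is the standardized per-allele effect
b = beta * sqrt(2 MAF (1 - MAF)) — the genotype-phenotype correlation
coefficient.  Heterogeneity between two populations is tested with a 1-df
Cochran Q on the impacts.  At ancestry-specific loci, the haplo-SNP
procedure walks from a sentinel that is common in one population but rare or
absent in the other to (ii) the shared transethnic "haplo-SNP" with the
strongest impact heterogeneity within +-500 kb and r^2 >= 0.1, and (iii) the
alternate ancestry-specific SNP in the second population tagging the same
haplotype, classifying the configuration as inverted / concordant / neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PopulationStats
from .loci import cluster_loci, MAX_GAP

#: region-wise haplo-SNP significance: genome-wide 5e-8 scaled from a 3-Gb
#: genome to a 1-Mb interval
def haplo_snp_threshold(
    genome_wide_p: float = 5e-8,
    genome_length: float = 3.0e9,
    interval: float = 1.0e6,
) -> float:
    """Region-wise significance threshold for haplo-SNP heterogeneity."""
    return genome_wide_p * (genome_length / interval)


HAPLO_SNP_P = haplo_snp_threshold()


def genetic_impact(beta, se, eaf):
    """Standardized allelic impact and its SE.

    b = beta * sqrt(2 maf (1 - maf)), maf = min(eaf, 1 - eaf); the SE scales
    by the same allele SD.  Monomorphic input (eaf of 0 or 1) is an error.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("monomorphic SNP: eaf must be strictly inside (0, 1)")
    maf = np.minimum(eaf, 1.0 - eaf)
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    return beta * sd, se * sd


def impact_het_test(b1, se1, b2, se2):
    """1-df Cochran Q on two standardized impacts; log-space tail P."""
    b1, se1, b2, se2 = (np.asarray(v, dtype=float) for v in (b1, se1, b2, se2))
    q = (b1 - b2) ** 2 / (se1**2 + se2**2)
    p = np.exp(sps.chi2.logsf(q, df=1))
    return q, p


def scan_heterogeneity(
    stats1: PopulationStats,
    stats2: PopulationStats,
    maf_min: float = 0.01,
    sig_p: float = 5e-8,
    suggestive_p: float = 1e-6,
) -> pd.DataFrame:
    """Genome-wide impact-heterogeneity scan over the shared SNP universe.

    Both inputs must be QC-passed and allele-aligned (same effect allele per
    shared SNP; mismatches raise).  SNPs rare (MAF < ``maf_min``) in either
    population are excluded.  Returns a per-SNP table with impacts, Q, P_HET,
    class labels (significant / suggestive / null) and a LOCUS id chaining
    labeled SNPs within 500 kb.
    """
    merged = stats1.table.merge(stats2.table, on="SNP", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("empty SNP universe intersection")
    if not (merged["EA_1"] == merged["EA_2"]).all():
        raise ValueError(
            "effect alleles differ between populations; run align_alleles first"
        )
    maf1 = np.minimum(merged["EAF_1"], 1 - merged["EAF_1"])
    maf2 = np.minimum(merged["EAF_2"], 1 - merged["EAF_2"])
    merged = merged[(maf1 >= maf_min) & (maf2 >= maf_min)].reset_index(drop=True)

    b1, se_b1 = genetic_impact(merged["BETA_1"], merged["SE_1"], merged["EAF_1"])
    b2, se_b2 = genetic_impact(merged["BETA_2"], merged["SE_2"], merged["EAF_2"])
    q, p = impact_het_test(b1, se_b1, b2, se_b2)

    out = pd.DataFrame(
        {
            "CHR": merged["CHR_1"].astype(str),
            "POS": merged["POS_1"],
            "SNP": merged["SNP"],
            "IMPACT_1": b1,
            "SE_IMPACT_1": se_b1,
            "IMPACT_2": b2,
            "SE_IMPACT_2": se_b2,
            "Q": q,
            "P_HET": p,
        }
    )
    out["LABEL"] = np.where(
        out["P_HET"] < sig_p,
        "significant",
        np.where(out["P_HET"] < suggestive_p, "suggestive", "null"),
    )
    out["LOCUS"] = -1
    labeled = out[out["LABEL"] != "null"]
    if len(labeled):
        for i, locus in enumerate(cluster_loci(labeled[["CHR", "POS", "SNP"]])):
            out.loc[out["SNP"].isin(locus.members), "LOCUS"] = i
    return out.sort_values(["CHR", "POS"]).reset_index(drop=True)


class HaploType(str, Enum):
    INVERTED = "inverted"
    CONCORDANT = "concordant"
    NEUTRAL = "neutral"
    UNRESOLVED = "unresolved"


@dataclass
class HaploSnpResult:
    """Outcome of the three-step ancestry-specific locus dissection."""

    index_sentinel: str
    index_population: int
    haplo_snp: str | None = None
    p_het: float = np.nan
    alternate_specific_snp: str | None = None
    type_label: HaploType = HaploType.UNRESOLVED
    effect_index: float = np.nan
    effect_second: float = np.nan

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_het) and self.p_het < HAPLO_SNP_P


def select_haplo_snp(
    sentinel: str,
    sentinel_pos: tuple[str, int],
    het_table: pd.DataFrame,
    ld_lookup,
    window: int = MAX_GAP,
    r2_min: float = 0.1,
) -> tuple[str, float] | None:
    """Step (ii): the transethnic SNP with the smallest heterogeneity P
    within +-window of and r^2 >= r2_min to the sentinel.

    ``het_table`` is a :func:`scan_heterogeneity` output (its rows are
    already restricted to SNPs non-rare in both populations);
    ``ld_lookup(a, b)`` returns r^2 in the index population's panel.
    Returns (snp, p_het) or None when no candidate qualifies.
    """
    chrom, pos = sentinel_pos
    cands = het_table[
        (het_table["CHR"] == chrom)
        & ((het_table["POS"] - pos).abs() <= window)
        & (het_table["SNP"] != sentinel)
    ]
    best = None
    for row in cands.itertuples(index=False):
        r2 = ld_lookup(sentinel, row.SNP)
        if r2 is None or r2 < r2_min:
            continue
        key = (row.P_HET, row.POS, row.SNP)
        if best is None or key < best[0]:
            best = (key, row.SNP, float(row.P_HET), int(row.POS))
    if best is None:
        return None
    # window/LD invariants re-checked on every call
    assert abs(best[3] - pos) <= window
    return best[1], best[2]


def select_alternate_specific_snp(
    haplo_snp: str,
    haplo_pos: tuple[str, int],
    stats_second: PopulationStats,
    ld_lookup,
    window: int = MAX_GAP,
    r2_min: float = 0.1,
) -> str | None:
    """Step (iii): smallest association P in the second population within
    +-window of and r^2 >= r2_min to the haplo-SNP (ties to smaller position).
    """
    chrom, pos = haplo_pos
    t = stats_second.table
    cands = t[(t["CHR"] == chrom) & ((t["POS"] - pos).abs() <= window)]
    best = None
    for row in cands.itertuples(index=False):
        r2 = ld_lookup(haplo_snp, row.SNP)
        if r2 is None or r2 < r2_min:
            continue
        key = (row.P, row.POS, row.SNP)
        if best is None or key < best[0]:
            best = (key, row.SNP)
    return None if best is None else best[1]


def classify_type(
    effect_index: float, effect_second: float, tau: float = 0.25
) -> HaploType:
    """Classify the ancestry-specific effect pair on the shared-haplotype
    orientation: neutral when the smaller |effect| is below ``tau`` times the
    larger, else inverted (opposite signs) or concordant."""
    e1, e2 = float(effect_index), float(effect_second)
    if e1 == 0.0 and e2 == 0.0:
        return HaploType.UNRESOLVED
    lo, hi = sorted((abs(e1), abs(e2)))
    if hi > 0 and lo / hi < tau:
        return HaploType.NEUTRAL
    if np.sign(e1) != np.sign(e2):
        return HaploType.INVERTED
    return HaploType.CONCORDANT


def haplo_snp_procedure(
    sentinel: str,
    index_population: int,
    stats1: PopulationStats,
    stats2: PopulationStats,
    ld1: "PanelLD",
    ld2: "PanelLD",
    het_table: pd.DataFrame | None = None,
    tau: float = 0.25,
) -> HaploSnpResult:
    """Run steps (ii)-(iii) from a given ancestry-specific sentinel and
    classify the resulting configuration.

    ``index_population`` is 1 or 2 — the population where the sentinel is
    polymorphic and associated.  Effects entering the type classification are
    the observed impacts of the sentinel (index population) and of the
    alternate SNP (second population), both oriented onto the haplo-SNP's
    effect-allele haplotype via the sign of their LD correlation with it.
    """
    from .gencorr import PanelLD  # noqa: F401 - typing only

    idx_stats, sec_stats = (stats1, stats2) if index_population == 1 else (stats2, stats1)
    idx_ld, sec_ld = (ld1, ld2) if index_population == 1 else (ld2, ld1)
    result = HaploSnpResult(index_sentinel=sentinel, index_population=index_population)

    srow = idx_stats.table.loc[idx_stats.table["SNP"] == sentinel]
    if srow.empty:
        return result
    srow = srow.iloc[0]
    if het_table is None:
        het_table = scan_heterogeneity(stats1, stats2)

    hit = select_haplo_snp(
        sentinel, (str(srow["CHR"]), int(srow["POS"])), het_table, idx_ld.r2
    )
    if hit is None:
        return result
    result.haplo_snp, result.p_het = hit
    hrow = het_table.loc[het_table["SNP"] == result.haplo_snp].iloc[0]

    alternate = select_alternate_specific_snp(
        result.haplo_snp,
        (str(hrow["CHR"]), int(hrow["POS"])),
        sec_stats,
        sec_ld.r2,
    )
    if alternate is None:
        return result
    result.alternate_specific_snp = alternate

    b_idx, _ = genetic_impact(srow["BETA"], srow["SE"], srow["EAF"])
    arow = sec_stats.table.loc[sec_stats.table["SNP"] == alternate].iloc[0]
    b_sec, _ = genetic_impact(arow["BETA"], arow["SE"], arow["EAF"])
    r_idx = idx_ld.r(sentinel, result.haplo_snp) or 0.0
    r_sec = sec_ld.r(alternate, result.haplo_snp) or 0.0
    result.effect_index = float(b_idx * np.sign(r_idx))
    result.effect_second = float(b_sec * np.sign(r_sec))
    result.type_label = classify_type(result.effect_index, result.effect_second, tau)
    return result
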