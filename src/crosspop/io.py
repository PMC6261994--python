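"""Readers/writers for GWAS summary statistics, haplotype reference panels and
genomic region files, plus allele harmonization.

Conventions
-----------
* Summary statistics are tab-delimited with canonical column names
  ``CHR POS SNP EA NEA EAF BETA SE P N INFO CALL_RATE``; a ``dialect`` mapping
  can rename arbitrary headers onto these.
* SNP positions are 1-based (GWAS/VCF convention).  BED regions are 0-based
  half-open; the conversion between the two happens only at overlap time
  (see :mod:`crosspop.selection`).
* ``ea`` is the effect allele; after :func:`align_alleles` it always equals the
  panel ALT allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical summary-statistic columns, in output order
SUMSTAT_COLUMNS = [
    "CHR", "POS", "SNP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N",
    "INFO", "CALL_RATE",
]
REQUIRED_COLUMNS = ["CHR", "POS", "SNP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryStatError(ValueError):
    """Configuration or content problem in a summary-statistic file."""


@dataclass
class ParseReport:
    """Bookkeeping for rows dropped while reading or harmonizing."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, count: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + count

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"{self.n_kept}/{self.n_read} rows kept"]
        parts += [f"{v} dropped ({k})" for k, v in sorted(self.dropped.items())]
        return "; ".join(parts)


@dataclass
class PopulationStats:
    """One population's per-SNP association records for one trait.

    ``table`` holds one row per SNP with the canonical columns; rows are kept
    sorted by (CHR, POS) and SNP ids are unique.
    """

    population: str
    trait: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = _normalize_table(self.table)

    @property
    def n_total(self) -> int:
        """Maximum per-SNP sample size."""
        return 0 if self.table.empty else int(self.table["N"].max())

    @property
    def maf(self) -> pd.Series:
        eaf = self.table["EAF"]
        return np.minimum(eaf, 1.0 - eaf)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ReferencePanel:
    """Phased 0/1 haplotypes (H x M) with per-SNP metadata.

    ``snp_meta`` columns: CHR, POS, SNP, REF, ALT, aligned 1:1 with the
    haplotype matrix columns.
    """

    population: str
    haplotypes: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D 0/1 matrix")
        if self.haplotypes.shape[1] != len(self.snp_meta):
            raise ValueError("snp_meta must align 1:1 with haplotype columns")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """ALT-allele frequency per column."""
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open interval [start, end)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos0 < self.end


def _normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    for col in ("INFO", "CALL_RATE"):
        if col not in table.columns:
            table[col] = np.nan
    table = table[SUMSTAT_COLUMNS]
    table = table.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)
    return table


def read_summary_stats(
    path,
    dialect: dict[str, str] | None = None,
    population: str = "",
    trait: str = "",
) -> tuple[PopulationStats, ParseReport]:
    """Read a tab-delimited summary-statistic file.

    Parameters
    ----------
    path
        Tab-delimited file with a header line.
    dialect
        Mapping from file column names to canonical names, e.g.
        ``{"chrom": "CHR", "pval": "P"}``.  Identity for canonical headers.

    Rows whose required fields fail to parse (non-numeric EAF/BETA/SE/P/N,
    missing alleles) are dropped and counted in the returned report.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.empty and raw.columns.empty:
        raise SummaryStatError(f"empty summary-statistic file: {path}")
    if dialect:
        raw = raw.rename(columns=dialect)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SummaryStatError(f"missing required column(s): {', '.join(missing)}")
    report = ParseReport(n_read=len(raw))
    if raw.empty:
        raise SummaryStatError(f"no data rows in summary-statistic file: {path}")

    out = pd.DataFrame()
    out["CHR"] = raw["CHR"].astype(str)
    out["SNP"] = raw["SNP"].astype(str)
    out["EA"] = raw["EA"].astype(str).str.upper()
    out["NEA"] = raw["NEA"].astype(str).str.upper()
    for col in ("POS", "EAF", "BETA", "SE", "P", "N"):
        out[col] = pd.to_numeric(raw[col], errors="coerce")
    for col in ("INFO", "CALL_RATE"):
        out[col] = (
            pd.to_numeric(raw[col], errors="coerce") if col in raw.columns else np.nan
        )

    bad = (
        out[["POS", "EAF", "BETA", "SE", "P", "N"]].isna().any(axis=1)
        | (out["SE"] <= 0)
        | (out["EAF"] < 0)
        | (out["EAF"] > 1)
        | (out["POS"] < 1)
        | (out["EA"] == out["NEA"])
    )
    if bad.any():
        report.drop("unparsable_or_invalid", int(bad.sum()))
        out = out[~bad]
    dup = out["SNP"].duplicated(keep="first")
    if dup.any():
        report.drop("duplicate_id", int(dup.sum()))
        out = out[~dup]
    out["POS"] = out["POS"].astype(np.int64)
    report.n_kept = len(out)
    logger.info("read %s: %s", path, report)
    stats = PopulationStats(population=population, trait=trait, table=out)
    return stats, report


def write_summary_stats(stats: PopulationStats, path) -> None:
    """Write canonical tab-delimited summary statistics (round-trip safe)."""
    stats.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def _is_strand_ambiguous(ea: str, nea: str) -> bool:
    return _COMPLEMENT.get(ea) == nea


def align_alleles(
    stats: PopulationStats,
    panel_meta: pd.DataFrame,
    drop_ambiguous: bool = True,
    ambiguous_maf: float = 0.4,
) -> tuple[PopulationStats, ParseReport]:
    """Orient every record's effect allele to the panel ALT allele.

    Matching is on (CHR, POS), with SNP id as tiebreak at multi-allelic sites.
    Where the input effect allele is the panel REF, beta is negated and EAF
    replaced by 1 - EAF.  Strand flips (complementary alleles) are resolved the
    same way.  Strand-ambiguous pairs (A/T, C/G) are dropped when
    ``drop_ambiguous`` and MAF > ``ambiguous_maf`` since frequency cannot then
    disambiguate the strand.  Idempotent: a second application is the identity.
    """
    meta = panel_meta.copy()
    meta["REF"] = meta["REF"].astype(str).str.upper()
    meta["ALT"] = meta["ALT"].astype(str).str.upper()
    dup_sites = meta.duplicated(subset=["CHR", "POS"], keep=False)
    by_pos = {
        (r.CHR, r.POS): r for r in meta[~dup_sites].itertuples(index=False)
    }
    by_pos_id = {
        (r.CHR, r.POS, r.SNP): r for r in meta[dup_sites].itertuples(index=False)
    }

    report = ParseReport(n_read=len(stats.table))
    rows = []
    for rec in stats.table.itertuples(index=False):
        key = (rec.CHR, rec.POS)
        panel = by_pos.get(key)
        if panel is None:
            panel = by_pos_id.get((rec.CHR, rec.POS, rec.SNP))
            if panel is None:
                reason = (
                    "multiallelic_unmatched" if key in {
                        (r.CHR, r.POS) for r in by_pos_id.values()
                    } else "unmatched"
                )
                report.drop(reason)
                continue
        ea, nea = rec.EA, rec.NEA
        maf = min(rec.EAF, 1.0 - rec.EAF)
        if drop_ambiguous and _is_strand_ambiguous(ea, nea) and maf > ambiguous_maf:
            report.drop("strand_ambiguous")
            continue
        flip = None  # True: swap effect/non-effect; False: already ALT
        if {ea, nea} == {panel.REF, panel.ALT}:
            flip = ea == panel.REF
        else:
            cea, cnea = _COMPLEMENT.get(ea), _COMPLEMENT.get(nea)
            if {cea, cnea} == {panel.REF, panel.ALT}:
                flip = cea == panel.REF
                ea, nea = cea, cnea
            else:
                report.drop("allele_mismatch")
                continue
        row = rec._asdict()
        row["EA"], row["NEA"] = ea, nea
        if flip:
            row["EA"], row["NEA"] = nea, ea
            row["BETA"] = -rec.BETA
            row["EAF"] = 1.0 - rec.EAF
        rows.append(row)
    table = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)
    report.n_kept = len(table)
    logger.info("align_alleles %s/%s: %s", stats.population, stats.trait, report)
    return replace(stats, table=table), report


def read_regions(path) -> list[GenomicRegion]:
    """Read a 3+ column BED file into 0-based half-open regions."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else ""
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: malformed interval start={start} >= end={end}"
                )
            regions.append(GenomicRegion(chrom, start, end, label))
    return regions


def write_regions(regions: list[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_panel_vcf(path, population: str = "") -> ReferencePanel:
    """Load a phased VCF into a reference panel (biallelic SNPs only)."""
    import pysam

    vcf = pysam.VariantFile(path)
    haps: list[list[int]] = []
    meta_rows = []
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        if len(rec.alts or ()) != 1:
            continue
        column: list[int] = []
        for sample in rec.samples.values():
            gt = sample["GT"]
            if gt is None or any(a is None for a in gt):
                column = []
                break
            column.extend(int(a) for a in gt)
        if not column:
            continue
        haps.append(column)
        meta_rows.append(
            {
                "CHR": str(rec.chrom),
                "POS": int(rec.pos),
                "SNP": rec.id or f"{rec.chrom}:{rec.pos}",
                "REF": rec.ref,
                "ALT": rec.alts[0],
            }
        )
    if not haps:
        raise ValueError(f"no usable biallelic phased records in {path}")
    matrix = np.array(haps, dtype=np.int8).T
    return ReferencePanel(population, matrix, pd.DataFrame(meta_rows))


def read_panel_table(hap_path, meta_path, population: str = "") -> ReferencePanel:
    """Load a whitespace-delimited 0/1 haplotype matrix + sidecar SNP table.

    The matrix file has one row per haplotype; the sidecar is tab-delimited
    with columns CHR POS SNP REF ALT, one row per matrix column.
    """
    matrix = np.loadtxt(hap_path, dtype=np.int8)
    matrix = np.atleast_2d(matrix)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"CHR": str})
    return ReferencePanel(population, matrix, meta)


def write_panel_table(panel: ReferencePanel, hap_path, meta_path) -> None:
    np.savetxt(hap_path, panel.haplotypes, fmt="%d")
    panel.snp_meta.to_csv(meta_path, sep="\t", index=False)
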