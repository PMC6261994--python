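"""Two-population synthetic GWAS data with controllable genetic architecture.

The generator produces every input the downstream analyses need without any
external data: Balding–Nichols allele-frequency divergence between the two
populations, block-structured LD from a per-block Gaussian-copula AR(1)
haplotype model, polygenic per-allele effects with MAF-dependent variance and
configurable cross-population correlation, LD-aware summary statistics, and
small individual-level cohorts.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PopulationStats, ReferencePanel, SUMSTAT_COLUMNS


@dataclass
class SimConfig:
    """Study conditions for the two-population simulation.

    Defaults emulate an East Asian / European style contrast: F_ST 0.11,
    per-population SNP heritabilities near 0.1, strong but imperfect
    cross-population effect correlation, and MAF exponent alpha = -1
    (equal expected per-SNP heritability on the standardized scale).
    """

    m_snps: int = 20_000
    n_blocks: int = 800
    rho_within: float = 0.9
    rho_range: tuple[float, float] | None = None
    fst: float = 0.11
    maf_floor: float = 0.01
    h2: tuple[float, float] = (0.107, 0.086)
    alpha: float = -1.0
    pi: float = 0.05
    rho_g: float = 0.9
    pop_specific_frac: float = 0.0
    n_gwas: tuple[int, int] = (50_000, 50_000)
    n_hap: int = 1_000
    genome_length: float = 3.0e9
    n_chrom: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if not (0.0 <= self.rho_within < 1.0):
            raise ValueError("rho_within must be in [0, 1)")
        if self.rho_range is not None and not (
            0.0 <= self.rho_range[0] <= self.rho_range[1] < 1.0
        ):
            raise ValueError("rho_range must satisfy 0 <= lo <= hi < 1")
        if not all(0.0 <= h <= 1.0 for h in self.h2):
            raise ValueError("h2 components must be in [0, 1]")
        if self.pi * self.m_snps < 1:
            raise ValueError("pi * m_snps must be >= 1")
        if min(self.m_snps, self.n_blocks, self.n_hap) <= 0:
            raise ValueError("counts must be positive")
        if self.n_hap % 2:
            raise ValueError("n_hap must be even (phased diploid haplotypes)")


def simulate_frequencies(
    m: int,
    fst: float,
    maf_floor: float,
    seed: int | np.random.Generator,
    ancestral: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ancestral and two per-population allele frequencies.

    Ancestral ALT frequencies are uniform on [maf_floor, 1 - maf_floor];
    each population's frequency is Balding–Nichols distributed,
    Beta(p(1-F)/F, (1-p)(1-F)/F), independently around the ancestral p, so
    that E[p_k] = p and Var[p_k] = F p (1 - p).  F = 0 returns the ancestral
    frequencies unchanged.
    """
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1); fst=1 is a degenerate Beta")
    rng = np.random.default_rng(seed)
    if ancestral is None:
        ancestral = rng.uniform(maf_floor, 1.0 - maf_floor, size=m)
    ancestral = np.asarray(ancestral, dtype=float)
    if fst == 0.0:
        return ancestral, ancestral.copy(), ancestral.copy()
    scale = (1.0 - fst) / fst
    a, b = ancestral * scale, (1.0 - ancestral) * scale
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    return ancestral, p1, p2


def assign_positions(
    m: int,
    n_blocks: int,
    genome_length: float,
    n_chrom: int,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign block ids, chromosomes and sorted physical positions.

    Blocks are contiguous, near-equal-size runs of SNPs; each block lives on
    one chromosome (round-robin), with sorted uniform positions within the
    chromosome so that physical-distance locus rules can be exercised.
    Returns (frame with CHR/POS/SNP/BLOCK, block id vector).
    """
    rng = np.random.default_rng(seed)
    block = np.repeat(np.arange(n_blocks), int(np.ceil(m / n_blocks)))[:m]
    chrom_len = genome_length / n_chrom
    chrom_of_block = np.arange(n_blocks) % n_chrom
    chrom = chrom_of_block[block]
    pos = np.empty(m, dtype=np.int64)
    for c in range(n_chrom):
        mask = chrom == c
        if not mask.any():
            continue
        draws = np.sort(rng.uniform(1, chrom_len, size=mask.sum()))
        pos[mask] = draws.astype(np.int64)
    frame = pd.DataFrame(
        {
            "CHR": [str(c + 1) for c in chrom],
            "POS": pos,
            "SNP": [f"snp{i}" for i in range(m)],
            "BLOCK": block,
        }
    )
    # keep positions sorted within (chromosome, block order)
    frame = frame.sort_values(["BLOCK", "POS"], kind="mergesort").reset_index(drop=True)
    frame["SNP"] = [f"snp{i}" for i in range(m)]
    return frame, frame["BLOCK"].to_numpy()


def _ar1_latent(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    innov_scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + innov_scale * rng.standard_normal(n)
    return z


def simulate_panel(
    freqs: np.ndarray,
    n_hap: int,
    block: np.ndarray,
    rho_within: float | np.ndarray,
    seed: int | np.random.Generator,
    snp_meta: pd.DataFrame | None = None,
    population: str = "",
) -> ReferencePanel:
    """Draw phased haplotypes by thresholding a per-block AR(1) Gaussian copula.

    Adjacent latent variables within a block have correlation ``rho_within``
    (a scalar, or one value per block for heterogeneous LD strength); blocks
    are independent.  Each SNP's latent variable is thresholded at the
    quantile matching its target ALT frequency, so realized column
    frequencies are binomial around the targets.  Frequencies of exactly 0
    or 1 yield monomorphic columns.
    """
    rho_within = np.asarray(rho_within, dtype=float)
    if np.any(rho_within >= 1.0):
        raise ValueError("rho_within must be < 1")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    m = freqs.size
    haps = np.empty((n_hap, m), dtype=np.int8)
    thresholds = stats.norm.ppf(np.clip(freqs, 0.0, 1.0))
    for i, b in enumerate(np.unique(block)):
        cols = np.flatnonzero(block == b)
        rho = float(rho_within) if rho_within.ndim == 0 else float(rho_within[i])
        z = _ar1_latent(rng, n_hap, cols.size, rho)
        haps[:, cols] = (z < thresholds[cols]).astype(np.int8)
    if snp_meta is None:
        snp_meta = pd.DataFrame(
            {
                "CHR": "1",
                "POS": np.arange(1, m + 1),
                "SNP": [f"snp{i}" for i in range(m)],
                "REF": "A",
                "ALT": "G",
                "BLOCK": block,
            }
        )
    else:
        snp_meta = snp_meta.copy()
        if "BLOCK" not in snp_meta.columns:
            snp_meta["BLOCK"] = block
        for col, default in (("REF", "A"), ("ALT", "G")):
            if col not in snp_meta.columns:
                snp_meta[col] = default
    return ReferencePanel(population, haps, snp_meta)


def simulate_effects(
    config: SimConfig,
    freqs: tuple[np.ndarray, np.ndarray],
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-allele causal effect vectors for both populations.

    A fraction ``pi`` of SNPs is causal.  Shared causal SNPs receive effects
    from a bivariate normal with correlation ``rho_g`` and per-SNP variance
    proportional to [2p(1-p)]^alpha (per-population frequency); a fraction
    ``pop_specific_frac`` of causal SNPs carries an effect in exactly one
    population.  Each population's effects are rescaled so the realized
    genetic variance sum(beta^2 * 2p(1-p)) over causal SNPs equals h2 exactly.
    SNPs monomorphic in a population get zero effect there.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p1, p2 = (np.asarray(f, dtype=float) for f in freqs)
    m = p1.size
    n_causal = int(round(config.pi * m))
    if n_causal < 1:
        raise ValueError("pi * m < 1: no causal SNPs")
    causal = rng.choice(m, size=n_causal, replace=False)

    n_spec = int(round(config.pop_specific_frac * n_causal))
    spec = rng.permutation(causal)[:n_spec]
    spec1_only = spec[: n_spec // 2]  # causal in population 1 only
    spec2_only = spec[n_spec // 2:]

    beta = np.zeros((2, m))
    z1 = rng.standard_normal(n_causal)
    z2 = config.rho_g * z1 + np.sqrt(1.0 - config.rho_g**2) * rng.standard_normal(
        n_causal
    )
    for k, (p, z) in enumerate(((p1, z1), (p2, z2))):
        het = 2.0 * p[causal] * (1.0 - p[causal])
        poly = het > 0
        sd = np.zeros(n_causal)
        sd[poly] = het[poly] ** (config.alpha / 2.0)
        beta[k, causal] = z * sd
    beta[0, spec2_only] = 0.0
    beta[1, spec1_only] = 0.0

    for k, p in enumerate((p1, p2)):
        var = np.sum(beta[k] ** 2 * 2.0 * p * (1.0 - p))
        if var > 0:
            beta[k] *= np.sqrt(config.h2[k] / var)
    return beta[0], beta[1], causal


def _block_correlation(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix over polymorphic columns; returns (R, poly mask)."""
    freqs = haps.mean(axis=0)
    poly = (freqs > 0) & (freqs < 1)
    if poly.sum() == 0:
        return np.empty((0, 0)), poly
    sub = haps[:, poly].astype(float)
    R = np.corrcoef(sub, rowvar=False)
    R = np.atleast_2d(R)
    return R, poly


def _safe_cholesky(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Cholesky with escalating ridge regularization for near-singular R."""
    import warnings

    ridge = 0.0
    for _ in range(12):
        try:
            return np.linalg.cholesky(R + ridge * np.eye(len(R)))
        except np.linalg.LinAlgError:
            if ridge:
                warnings.warn(f"LD matrix singular; ridge {ridge:g} insufficient")
            ridge = eps if ridge == 0.0 else ridge * 10.0
    raise np.linalg.LinAlgError("LD matrix not positive definite even after ridge")


def simulate_summary_stats(
    panel: ReferencePanel,
    beta: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    trait: str = "SBP",
) -> PopulationStats:
    """Draw LD-aware GWAS summary statistics from a panel and causal effects.

    Per block, marginal standardized effects are R b (R the block LD
    correlation matrix, b = beta * sqrt(2p(1-p)) the standardized causal
    effects); Z is multivariate normal with mean sqrt(n) R b and covariance R.
    Emitted per-SNP records have BETA = Z / (sqrt(n) sigma) and
    SE = 1 / (sqrt(n) sigma) with sigma = sqrt(2p(1-p)) from panel
    frequencies.  Monomorphic SNPs are skipped.
    """
    rng = np.random.default_rng(seed)
    meta = panel.snp_meta
    block = meta["BLOCK"].to_numpy()
    freqs = panel.frequencies
    sigma = np.sqrt(2.0 * freqs * (1.0 - freqs))
    b_std = beta * sigma

    z = np.full(panel.n_snps, np.nan)
    for blk in np.unique(block):
        cols = np.flatnonzero(block == blk)
        R, poly = _block_correlation(panel.haplotypes[:, cols])
        if R.size == 0:
            continue
        idx = cols[poly]
        mean = np.sqrt(n) * R @ b_std[idx]
        L = _safe_cholesky(R)
        z[idx] = mean + L @ rng.standard_normal(idx.size)

    keep = ~np.isnan(z)
    zk = z[keep]
    sig = sigma[keep]
    with np.errstate(divide="ignore"):
        logp = stats.chi2.logsf(zk**2, df=1)
    table = pd.DataFrame(
        {
            "CHR": meta.loc[keep, "CHR"].astype(str).to_numpy(),
            "POS": meta.loc[keep, "POS"].to_numpy(),
            "SNP": meta.loc[keep, "SNP"].to_numpy(),
            "EA": meta.loc[keep, "ALT"].to_numpy(),
            "NEA": meta.loc[keep, "REF"].to_numpy(),
            "EAF": freqs[keep],
            "BETA": zk / (np.sqrt(n) * sig),
            "SE": 1.0 / (np.sqrt(n) * sig),
            "P": np.exp(logp),
            "N": n,
            "INFO": 1.0,
            "CALL_RATE": 1.0,
        }
    )[SUMSTAT_COLUMNS]
    return PopulationStats(panel.population, trait, table)


@dataclass
class CohortConfig:
    """Phenotype model for individual-level cohort simulation (mmHg units)."""

    sbp_intercept: float = 130.0
    dbp_intercept: float = 80.0
    sbp_noise_sd: float = 15.0
    dbp_noise_sd: float = 10.0
    dbp_beta_scale: float = 0.6
    age_range: tuple[float, float] = (40.0, 75.0)
    sbp_age_effect: float = 0.5
    dbp_age_effect: float = 0.2
    treated_frac: float = 0.2


@dataclass
class Cohort:
    """Individual-level genotypes and phenotypes."""

    genotypes: np.ndarray  # n_ind x m, allele dose 0/1/2
    phenotypes: pd.DataFrame  # SBP, DBP, TREATED, AGE, ONSET_AGE
    snp_meta: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_cohort(
    n_ind: int,
    freqs: np.ndarray,
    beta: np.ndarray,
    seed: int | np.random.Generator,
    config: CohortConfig | None = None,
) -> Cohort:
    """Simulate genotypes ~ Binomial(2, p) and blood-pressure phenotypes.

    SBP = intercept + G beta + age effect + Gaussian noise; DBP uses the same
    genetic values scaled by ``dbp_beta_scale``.  A ``treated_frac`` fraction
    of individuals is flagged treated, with onset age below their current age.
    """
    if n_ind < 10:
        raise ValueError("n_ind must be >= 10")
    config = config or CohortConfig()
    if config.sbp_noise_sd < 0 or config.dbp_noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    g = rng.binomial(2, freqs, size=(n_ind, freqs.size)).astype(np.int8)
    genetic = g @ np.asarray(beta, dtype=float)
    age = rng.uniform(*config.age_range, size=n_ind)
    sbp = (
        config.sbp_intercept
        + genetic
        + config.sbp_age_effect * (age - np.mean(config.age_range))
        + config.sbp_noise_sd * rng.standard_normal(n_ind)
    )
    dbp = (
        config.dbp_intercept
        + config.dbp_beta_scale * genetic
        + config.dbp_age_effect * (age - np.mean(config.age_range))
        + config.dbp_noise_sd * rng.standard_normal(n_ind)
    )
    treated = rng.uniform(size=n_ind) < config.treated_frac
    hypertensive = treated | (sbp >= 160.0) | (dbp >= 100.0)
    onset = np.where(hypertensive, age - rng.uniform(1.0, 15.0, size=n_ind), np.nan)
    pheno = pd.DataFrame(
        {"SBP": sbp, "DBP": dbp, "TREATED": treated, "AGE": age, "ONSET_AGE": onset}
    )
    return Cohort(genotypes=g, phenotypes=pheno)


@dataclass
class TwoPopulationStudy:
    """A complete synthetic two-population GWAS: panels, effects, sumstats."""

    config: SimConfig
    panels: tuple[ReferencePanel, ReferencePanel]
    frequencies: tuple[np.ndarray, np.ndarray]
    betas: tuple[np.ndarray, np.ndarray]
    causal: np.ndarray
    stats: tuple[PopulationStats, PopulationStats]


def simulate_two_population_study(
    config: SimConfig,
    panels: tuple[ReferencePanel, ReferencePanel] | None = None,
    seed: int | None = None,
) -> TwoPopulationStudy:
    """Run the full generator pipeline for both populations.

    Passing pre-built ``panels`` reuses the LD structure across replicates,
    which mirrors real studies where the reference panel is fixed while
    effect draws and sampling noise vary.

    Causal effects are drawn against the panels' realized frequencies, so
    the target heritability refers to SNPs observable in the panels (a SNP
    monomorphic in a panel cannot carry heritability there).  When
    ``config.rho_range`` is set, each LD block draws its own within-block
    correlation uniformly from the range — shared between the populations —
    giving the heterogeneous spread of LD scores real genomes show.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if panels is None:
        _, p1, p2 = simulate_frequencies(
            config.m_snps, config.fst, config.maf_floor, rng
        )
        meta, block = assign_positions(
            config.m_snps, config.n_blocks, config.genome_length, config.n_chrom, rng
        )
        if config.rho_range is not None:
            rho = rng.uniform(*config.rho_range, size=config.n_blocks)
        else:
            rho = config.rho_within
        panels = (
            simulate_panel(p1, config.n_hap, block, rho, rng,
                           snp_meta=meta, population="POP1"),
            simulate_panel(p2, config.n_hap, block, rho, rng,
                           snp_meta=meta, population="POP2"),
        )
    frequencies = (panels[0].frequencies, panels[1].frequencies)
    b1, b2, causal = simulate_effects(config, frequencies, rng)
    s1 = simulate_summary_stats(panels[0], b1, config.n_gwas[0], rng)
    s2 = simulate_summary_stats(panels[1], b2, config.n_gwas[1], rng)
    return TwoPopulationStudy(config, panels, frequencies, (b1, b2), causal, (s1, s2))


def simulate_ancestry_specific_locus(
    seed: int | np.random.Generator,
    n: int = 100_000,
    m_region: int = 51,
    rho_within: float = 0.95,
    impact: float = 0.02,
    n_hap: int = 2_000,
    spacing: int = 10_000,
    idx_private1: int = 20,
    idx_private2: int = 30,
) -> dict:
    """Plant a common ancestry-specific variant pair on a shared haplotype.

    One causal SNP private to population 1 (monomorphic in population 2) with
    standardized impact ``+impact`` and an opposite-effect causal SNP private
    to population 2 sit on a shared AR(1) haplotype block.  Shared SNPs in
    between act as transethnic haplo-SNP candidates whose marginal effects are
    pulled in opposite directions in the two populations.

    Returns panels, summary statistics and the ids of the planted SNPs.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.2, 0.5, size=m_region)
    p1 = p_anc.copy()
    p2 = p_anc.copy()
    p1[idx_private2] = 0.0  # population-2 private SNP absent in population 1
    p2[idx_private1] = 0.0
    block = np.zeros(m_region, dtype=int)
    meta = pd.DataFrame(
        {
            "CHR": "1",
            "POS": np.arange(1, m_region + 1) * spacing,
            "SNP": [f"rs{i}" for i in range(m_region)],
            "REF": "A",
            "ALT": "G",
            "BLOCK": block,
        }
    )
    panel1 = simulate_panel(p1, n_hap, block, rho_within, rng, meta, "POP1")
    panel2 = simulate_panel(p2, n_hap, block, rho_within, rng, meta, "POP2")

    f1 = panel1.frequencies
    f2 = panel2.frequencies
    beta1 = np.zeros(m_region)
    beta2 = np.zeros(m_region)
    sd1 = np.sqrt(2 * f1[idx_private1] * (1 - f1[idx_private1]))
    sd2 = np.sqrt(2 * f2[idx_private2] * (1 - f2[idx_private2]))
    beta1[idx_private1] = impact / sd1
    beta2[idx_private2] = -impact / sd2

    stats1 = simulate_summary_stats(panel1, beta1, n, rng)
    stats2 = simulate_summary_stats(panel2, beta2, n, rng)
    return {
        "panels": (panel1, panel2),
        "stats": (stats1, stats2),
        "sentinel": f"rs{idx_private1}",
        "private_snp2": f"rs{idx_private2}",
    }
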