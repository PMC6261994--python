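"""SNP heritability and transethnic genetic correlation from summary
statistics, with MAF- and LD-dependent per-SNP heritability.

The estimator is a cross-population generalization of LD-score regression.
For population k with per-SNP chi-square statistics and generalized LD scores
l~_ki = sum_j r_k(i,j)^2 w_kj (weights w_kj = [2 p_kj (1-p_kj)]^(1+alpha)
times an LD-score-bin multiplier, mean-normalized), the moments are

    E[chi^2_ki] = 1 + N_k h2_k l~_ki / M            (within population)
    E[Z_1i Z_2i] = sqrt(N1 N2) rho sqrt(h2_1 h2_2) l~x_i / M   (cross)

where l~x_i = sum_j r_1(i,j) r_2(i,j) sqrt(w_1j w_2j) uses signed
r-products and geometric-mean weights.  h2_k and the coheritability are
fitted by weighted regressions; rho is their ratio, with a 200-block
ratio-of-totals jackknife SE.  Both the correlation of allelic impacts and
the correlation of per-allele effect sizes are reported; the two coincide
when the populations' allele frequencies coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PopulationStats, ReferencePanel

#: default number of contiguous jackknife blocks
JACKKNIFE_BLOCKS = 200


class PanelLD:
    """Signed LD lookup between named SNPs of one reference panel."""

    def __init__(self, panel: ReferencePanel):
        self._haps = panel.haplotypes.astype(float)
        freqs = panel.frequencies
        self._poly = (freqs > 0) & (freqs < 1)
        self._index = {s: i for i, s in enumerate(panel.snp_meta["SNP"])}

    def r(self, snp_a: str, snp_b: str) -> float | None:
        """Pearson correlation of allele indicators; None if unavailable."""
        ia, ib = self._index.get(snp_a), self._index.get(snp_b)
        if ia is None or ib is None or not (self._poly[ia] and self._poly[ib]):
            return None
        if ia == ib:
            return 1.0
        return float(np.corrcoef(self._haps[:, ia], self._haps[:, ib])[0, 1])

    def r2(self, snp_a: str, snp_b: str) -> float | None:
        r = self.r(snp_a, snp_b)
        return None if r is None else r * r


@dataclass
class HeritabilityModel:
    """Per-SNP heritability model: MAF exponent and LD-bin multipliers.

    alpha = -1 gives equal expected per-SNP heritability on the standardized
    scale (the GCTA convention); ld_bin_weights multiply the per-SNP variance
    by LD-score quantile bin and are mean-normalized before use.
    """

    h2_1: float = np.nan
    h2_2: float = np.nan
    alpha: float = -1.0
    ld_bin_weights: np.ndarray = field(default_factory=lambda: np.ones(5))
    m_eff: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.ld_bin_weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("ld_bin_weights must be positive")
        self.ld_bin_weights = w / w.mean()


@dataclass
class LdScores:
    """Per-SNP LD scores for the SNPs shared between the two panels.

    Score sums for population k run over *all* SNPs polymorphic in panel k
    (a pop-exclusive SNP still contributes association signal to its shared
    neighbors); the cross sums run over the shared set, where both effects
    can be nonzero.  ``m1``/``m2`` count each panel's polymorphic SNPs and
    normalize the per-SNP heritability; ``mx`` is their geometric mean.

    Columns of ``table``: SNP, CHR, POS, ELL1, ELL2, ELLX (plain scores),
    LT1, LT2, LTX (generalized, weight-augmented scores), W1, W2 (normalized
    per-SNP variance weights), SIGMA1, SIGMA2 (allele SDs).
    """

    table: pd.DataFrame
    m1: int
    m2: int

    @property
    def mx(self) -> float:
        return float(np.sqrt(self.m1 * self.m2))


def _per_snp_weights(freqs: np.ndarray, ell: np.ndarray, model: HeritabilityModel):
    het = 2.0 * freqs * (1.0 - freqs)
    w = het ** (1.0 + model.alpha)
    n_bins = len(model.ld_bin_weights)
    # quantile bins of the plain LD score
    edges = np.quantile(ell, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, ell, side="right")
    w = w * model.ld_bin_weights[bins]
    return w / w.mean()


def compute_ld_scores(
    panel1: ReferencePanel,
    panel2: ReferencePanel,
    model: HeritabilityModel | None = None,
    window: int = 1_000_000,
) -> LdScores:
    """Within- and cross-population LD scores over the shared SNP set.

    Scores are summed over SNPs in the same LD block when the panels carry a
    BLOCK column (the simulator's convention), otherwise over a +-``window``
    bp physical window.  The own-SNP term (r = 1) is included.  SNPs
    monomorphic in either panel are excluded from the shared universe.
    """
    model = model or HeritabilityModel()
    f1_all, f2_all = panel1.frequencies, panel2.frequencies
    meta1, meta2 = panel1.snp_meta, panel2.snp_meta
    ids1 = meta1["SNP"].to_numpy()
    ids2 = meta2["SNP"].to_numpy()
    poly1 = (f1_all > 0) & (f1_all < 1)
    poly2 = (f2_all > 0) & (f2_all < 1)
    poly2_of = dict(zip(ids2, poly2))
    col2_of = {s: i for i, s in enumerate(ids2)}
    # panel1 column order drives everything; universe_k = polymorphic in k
    shared_mask = np.array(
        [poly1[i] and poly2_of.get(s, False) for i, s in enumerate(ids1)]
    )
    if not shared_mask.any():
        raise ValueError("no shared polymorphic SNPs between panels")
    m1 = int(poly1.sum())
    m2 = int(poly2.sum())

    if "BLOCK" in meta1.columns:
        groups = meta1["BLOCK"].to_numpy()
    else:
        # window-based pseudo-blocks: same chromosome, chained within window
        chrom = meta1["CHR"].to_numpy()
        pos = meta1["POS"].to_numpy()
        new_group = np.ones(len(meta1), dtype=bool)
        new_group[1:] = (chrom[1:] != chrom[:-1]) | (
            np.abs(pos[1:] - pos[:-1]) > window
        )
        groups = np.cumsum(new_group) - 1

    h1 = panel1.haplotypes.astype(float)
    h2 = panel2.haplotypes.astype(float)
    # plain within-population scores (needed for the LD-score weight bins)
    ell1_u = np.full(len(ids1), np.nan)  # indexed by panel1 columns
    ell2_u = np.full(len(ids2), np.nan)  # indexed by panel2 columns
    for g in np.unique(groups):
        in_block = groups == g
        u1 = np.flatnonzero(in_block & poly1)
        if u1.size:
            r1 = np.atleast_2d(np.corrcoef(h1[:, u1], rowvar=False))
            ell1_u[u1] = np.sum(r1**2, axis=1)
        u2 = np.array(
            [col2_of[s] for s in ids1[in_block] if poly2_of.get(s, False)],
            dtype=int,
        )
        if u2.size:
            r2 = np.atleast_2d(np.corrcoef(h2[:, u2], rowvar=False))
            ell2_u[u2] = np.sum(r2**2, axis=1)

    w1_u = np.full(len(ids1), np.nan)
    w1_u[poly1] = _per_snp_weights(f1_all[poly1], ell1_u[poly1], model)
    w2_u = np.full(len(ids2), np.nan)
    w2_u[poly2] = _per_snp_weights(f2_all[poly2], ell2_u[poly2], model)

    # generalized scores at the shared (regression) SNPs: within-population
    # sums run over each panel's full polymorphic universe, cross sums over
    # the shared set with geometric-mean weights
    n_shared = int(shared_mask.sum())
    out_ell1 = np.empty(n_shared)
    out_ell2 = np.empty(n_shared)
    out_ellx = np.empty(n_shared)
    out_lt1 = np.empty(n_shared)
    out_lt2 = np.empty(n_shared)
    out_ltx = np.empty(n_shared)
    row_of = {}  # panel1 column -> output row
    for row, col in enumerate(np.flatnonzero(shared_mask)):
        row_of[col] = row
    for g in np.unique(groups):
        in_block = groups == g
        sh1 = np.flatnonzero(in_block & shared_mask)
        if sh1.size == 0:
            continue
        rows = np.array([row_of[c] for c in sh1])
        u1 = np.flatnonzero(in_block & poly1)
        r1_u = np.atleast_2d(np.corrcoef(h1[:, u1], rowvar=False))
        pick1 = np.searchsorted(u1, sh1)
        out_ell1[rows] = np.sum(r1_u[pick1] ** 2, axis=1)
        out_lt1[rows] = r1_u[pick1] ** 2 @ w1_u[u1]

        sh2 = np.array([col2_of[s] for s in ids1[sh1]], dtype=int)
        u2_ids = [s for s in ids1[in_block] if poly2_of.get(s, False)]
        u2 = np.array([col2_of[s] for s in u2_ids], dtype=int)
        r2_u = np.atleast_2d(np.corrcoef(h2[:, u2], rowvar=False))
        pick2 = np.array([np.flatnonzero(u2 == c)[0] for c in sh2])
        out_ell2[rows] = np.sum(r2_u[pick2] ** 2, axis=1)
        out_lt2[rows] = r2_u[pick2] ** 2 @ w2_u[u2]

        # cross: restrict both correlation matrices to the shared SNPs
        r1_s = r1_u[np.ix_(pick1, pick1)]
        shared_in_u2 = np.array(
            [np.flatnonzero(u2 == c)[0] for c in sh2]
        )
        r2_s = r2_u[np.ix_(shared_in_u2, shared_in_u2)]
        wx = np.sqrt(w1_u[sh1] * w2_u[sh2])
        out_ellx[rows] = np.sum(r1_s * r2_s, axis=1)
        out_ltx[rows] = (r1_s * r2_s) @ wx

    sh_cols1 = np.flatnonzero(shared_mask)
    sh_cols2 = np.array([col2_of[s] for s in ids1[sh_cols1]], dtype=int)
    f1 = f1_all[sh_cols1]
    f2 = f2_all[sh_cols2]
    table = pd.DataFrame(
        {
            "SNP": ids1[sh_cols1],
            "CHR": meta1.loc[shared_mask, "CHR"].to_numpy(),
            "POS": meta1.loc[shared_mask, "POS"].to_numpy(),
            "ELL1": out_ell1,
            "ELL2": out_ell2,
            "ELLX": out_ellx,
            "LT1": out_lt1,
            "LT2": out_lt2,
            "LTX": out_ltx,
            "W1": w1_u[sh_cols1],
            "W2": w2_u[sh_cols2],
            "SIGMA1": np.sqrt(2 * f1 * (1 - f1)),
            "SIGMA2": np.sqrt(2 * f2 * (1 - f2)),
        }
    )
    return LdScores(table=table, m1=m1, m2=m2)


def _block_edges(m: int, n_blocks: int) -> np.ndarray:
    n_blocks = min(n_blocks, m)
    return np.linspace(0, m, n_blocks + 1).astype(int)[:-1]


def _wls_slope_sums(y, x, w, edges):
    """Per-jackknife-block sufficient statistics of a weighted regression
    of y on [1, x]: returns arrays of block sums (Sw, Sx, Sy, Sxx, Sxy)."""
    return tuple(
        np.add.reduceat(v, edges)
        for v in (w, w * x, w * y, w * x * x, w * x * y)
    )


def _slope_intercept(sums):
    sw, sx, sy, sxx, sxy = sums
    denom = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / sw
    return slope, intercept


def _slope_no_intercept(sums):
    _, _, _, sxx, sxy = sums
    return sxy / sxx


def estimate_h2(
    stats: PopulationStats,
    scores: LdScores,
    model: HeritabilityModel | None = None,
    population: int = 1,
    n_jackknife: int = JACKKNIFE_BLOCKS,
) -> tuple[float, float, float]:
    """SNP heritability by weighted regression of chi-square on the
    generalized LD score.

    Fits E[chi2_i] = intercept + N_i h2 l~_i / M with regression weights
    1/(2 (1 + N h2 l~ / M)^2) updated once from a first-pass fit.  Returns
    (h2, jackknife SE, intercept).  Negative fitted h2 is reported as-is.
    """
    model = model or HeritabilityModel()
    lt_col = f"LT{population}"
    aligned = stats.table.merge(scores.table[["SNP", lt_col]], on="SNP")
    if aligned.empty:
        raise ValueError("no overlap between summary statistics and LD scores")
    z = (aligned["BETA"] / aligned["SE"]).to_numpy()
    chi2 = z * z
    n = aligned["N"].to_numpy(dtype=float)
    m_pop = scores.m1 if population == 1 else scores.m2
    x = n * aligned[lt_col].to_numpy() / m_pop

    edges = _block_edges(len(chi2), n_jackknife)
    sums0 = _wls_slope_sums(chi2, x, np.ones_like(chi2), edges)
    h2_first, _ = _slope_intercept(tuple(s.sum() for s in sums0))
    w = 1.0 / (2.0 * (1.0 + np.maximum(h2_first, 0.0) * x) ** 2)
    sums = _wls_slope_sums(chi2, x, w, edges)
    totals = tuple(s.sum() for s in sums)
    h2_hat, intercept = _slope_intercept(totals)

    # delete-one-block estimates
    h2_del = np.empty(len(edges))
    for b in range(len(edges)):
        t = tuple(tot - s[b] for tot, s in zip(totals, sums))
        h2_del[b], _ = _slope_intercept(t)
    n_b = len(edges)
    se = float(np.sqrt((n_b - 1) / n_b * np.sum((h2_del - h2_del.mean()) ** 2)))
    return float(h2_hat), se, float(intercept)


@dataclass
class CorrelationEstimate:
    """Transethnic genetic correlation with jackknife uncertainty."""

    rho: float
    se_rho: float
    mode: str  # "impact" or "effect"
    h2_1: float = np.nan
    se_h2_1: float = np.nan
    h2_2: float = np.nan
    se_h2_2: float = np.nan
    coheritability: float = np.nan
    p_vs_one: float = np.nan

    @property
    def rho_clipped(self) -> float:
        """rho clipped to [-1, 1] for reporting; raw value kept in .rho."""
        return float(np.clip(self.rho, -1.0, 1.0))


def wald_test_vs_one(rho: float, se_rho: float) -> float:
    """One-sided upper-tail normal P for the hypothesis rho < 1."""
    if se_rho <= 0:
        raise ValueError("se_rho must be positive")
    return float(sps.norm.sf((1.0 - rho) / se_rho))


def estimate_rho(
    stats1: PopulationStats,
    stats2: PopulationStats,
    scores: LdScores,
    model: HeritabilityModel | None = None,
    mode: str = "impact",
    n_jackknife: int = JACKKNIFE_BLOCKS,
    intercept_cross: float = 0.0,
    intercept_h2: float | None = None,
) -> CorrelationEstimate:
    """Transethnic genetic correlation from two aligned summary-stat sets.

    Fits the cross moment E[Z1 Z2] = sqrt(N1 N2) C l~x / M (C the
    coheritability; the cross intercept is fixed at ``intercept_cross``,
    zero for non-overlapping cohorts) alongside the two within-population
    heritability regressions, and reports rho = C / sqrt(h2_1 h2_2) with a
    ratio-of-totals jackknife over ``n_jackknife`` contiguous SNP blocks.

    ``mode="impact"`` correlates standardized (per-SD-genotype) effects;
    ``mode="effect"`` correlates per-allele effects, which reweights the
    aggregation by each SNP's pair of allele SDs.  The modes coincide when
    the two populations share allele frequencies.

    ``intercept_h2``, when given, fixes the within-population regression
    intercepts (e.g. to 1 for confounding-free data) instead of estimating
    them.
    """
    if mode not in ("impact", "effect"):
        raise ValueError("mode must be 'impact' or 'effect'")
    model = model or HeritabilityModel()
    merged = stats1.table.merge(
        stats2.table, on="SNP", suffixes=("_1", "_2")
    ).merge(scores.table, on="SNP")
    if merged.empty:
        raise ValueError("empty shared SNP universe")
    z1 = (merged["BETA_1"] / merged["SE_1"]).to_numpy()
    z2 = (merged["BETA_2"] / merged["SE_2"]).to_numpy()
    n1 = merged["N_1"].to_numpy(dtype=float)
    n2 = merged["N_2"].to_numpy(dtype=float)
    x1 = n1 * merged["LT1"].to_numpy() / scores.m1
    x2 = n2 * merged["LT2"].to_numpy() / scores.m2
    xx = np.sqrt(n1 * n2) * merged["LTX"].to_numpy() / scores.mx

    edges = _block_edges(len(z1), n_jackknife)
    n_b = len(edges)

    # first-pass unweighted fits for the variance weights
    def _first(y, x):
        sums = _wls_slope_sums(y, x, np.ones_like(y), edges)
        return _slope_intercept(tuple(s.sum() for s in sums))[0]

    h1_0 = max(_first(z1**2, x1), 0.0)
    h2_0 = max(_first(z2**2, x2), 0.0)
    c_0 = _first(z1 * z2, xx)
    var1 = 1.0 + h1_0 * x1
    var2 = 1.0 + h2_0 * x2
    w_1 = 1.0 / (2.0 * var1**2)
    w_2 = 1.0 / (2.0 * var2**2)
    w_x = 1.0 / (var1 * var2 + (c_0 * xx) ** 2)

    if intercept_h2 is None:
        fit_h2 = _slope_intercept
        y1, y2 = z1**2, z2**2
    else:
        fit_h2 = lambda sums: (_slope_no_intercept(sums), intercept_h2)  # noqa: E731
        y1, y2 = z1**2 - intercept_h2, z2**2 - intercept_h2
    sums1 = _wls_slope_sums(y1, x1, w_1, edges)
    sums2 = _wls_slope_sums(y2, x2, w_2, edges)
    sumsx = _wls_slope_sums(z1 * z2 - intercept_cross, xx, w_x, edges)
    tot1 = tuple(s.sum() for s in sums1)
    tot2 = tuple(s.sum() for s in sums2)
    totx = tuple(s.sum() for s in sumsx)

    h2_1_hat, _ = fit_h2(tot1)
    h2_2_hat, _ = fit_h2(tot2)
    c_hat = _slope_no_intercept(totx)
    if h2_1_hat <= 0 or h2_2_hat <= 0:
        raise ValueError(
            "non-positive heritability estimate; rho undefined "
            f"(h2_1={h2_1_hat:.4f}, h2_2={h2_2_hat:.4f})"
        )

    w1v = merged["W1"].to_numpy()
    w2v = merged["W2"].to_numpy()
    s1v = merged["SIGMA1"].to_numpy()
    s2v = merged["SIGMA2"].to_numpy()
    gam = np.sqrt(w1v * w2v)

    def _rho(c, h1, h2):
        if mode == "impact":
            return c / np.sqrt(h1 * h2)
        # effect mode: per-SNP covariance/variance profiles rescaled by the
        # allele SDs before aggregation
        num = c * np.sum(gam / (s1v * s2v)) / np.sum(gam)
        den = np.sqrt(
            h1 * np.mean(w1v / s1v**2) * h2 * np.mean(w2v / s2v**2)
        )
        return num / den

    rho_hat = _rho(c_hat, h2_1_hat, h2_2_hat)

    rho_del = np.empty(n_b)
    h1_del = np.empty(n_b)
    h2_del = np.empty(n_b)
    for b in range(n_b):
        t1 = tuple(tot - s[b] for tot, s in zip(tot1, sums1))
        t2 = tuple(tot - s[b] for tot, s in zip(tot2, sums2))
        tx = tuple(tot - s[b] for tot, s in zip(totx, sumsx))
        h1_del[b], _ = fit_h2(t1)
        h2_del[b], _ = fit_h2(t2)
        c_del = _slope_no_intercept(tx)
        rho_del[b] = _rho(c_del, max(h1_del[b], 1e-12), max(h2_del[b], 1e-12))
    fac = (n_b - 1) / n_b
    se_rho = float(np.sqrt(fac * np.sum((rho_del - rho_del.mean()) ** 2)))
    se_h1 = float(np.sqrt(fac * np.sum((h1_del - h1_del.mean()) ** 2)))
    se_h2 = float(np.sqrt(fac * np.sum((h2_del - h2_del.mean()) ** 2)))
    # jackknife bias correction removes the O(1/B) inflation of the ratio
    rho_hat = n_b * rho_hat - (n_b - 1) * rho_del.mean()

    return CorrelationEstimate(
        rho=float(rho_hat),
        se_rho=se_rho,
        mode=mode,
        h2_1=float(h2_1_hat),
        se_h2_1=se_h1,
        h2_2=float(h2_2_hat),
        se_h2_2=se_h2,
        coheritability=float(c_hat),
        p_vs_one=wald_test_vs_one(float(rho_hat), se_rho) if se_rho > 0 else np.nan,
    )
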