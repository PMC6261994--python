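"""Study-level QC, inflation correction, fixed-effects meta-analysis and
multi-stage signal validation.

The workflow mirrors standard multi-stage GWAS practice: per-study QC
(call rate, imputation quality, MAF), genomic-control lambda and LD-score
intercept diagnostics, chi-square correction by whichever factor the study's
sample size selects, inverse-variance-weighted pooling with Cochran's Q
heterogeneity, a reporting filter, follow-up selection, and a four-criterion
validation rule for sentinel SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PopulationStats, ParseReport

#: median of the 1-df chi-square distribution
CHI2_1_MEDIAN = 0.45494

#: default QC thresholds: (min call rate, min imputation R2, min MAF)
DEFAULT_QC = (0.95, 0.5, 0.01)

#: stage-1 follow-up P threshold
FOLLOWUP_P = 1.6e-5

#: genome-wide significance
GENOME_WIDE_P = 5e-8


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tests (e.g. replication lookups,
    group-wise heterogeneity testing)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def qc_filter(
    stats_in: PopulationStats,
    thresholds: tuple[float, float, float] = DEFAULT_QC,
) -> tuple[PopulationStats, ParseReport]:
    """Remove SNPs with call rate, imputation quality or MAF below threshold.

    All three comparisons are strict (a record exactly at a threshold is
    retained).  Records with missing INFO or CALL_RATE pass those checks.
    """
    min_call, min_info, min_maf = thresholds
    t = stats_in.table
    maf = np.minimum(t["EAF"], 1.0 - t["EAF"])
    fail_call = t["CALL_RATE"].notna() & (t["CALL_RATE"] < min_call)
    fail_info = t["INFO"].notna() & (t["INFO"] < min_info)
    fail_maf = maf < min_maf
    report = ParseReport(n_read=len(t))
    # a record is counted once, by the first criterion it fails
    if fail_call.any():
        report.drop("call_rate", int(fail_call.sum()))
    if (fail_info & ~fail_call).any():
        report.drop("imputation", int((fail_info & ~fail_call).sum()))
    if (fail_maf & ~fail_call & ~fail_info).any():
        report.drop("maf", int((fail_maf & ~fail_call & ~fail_info).sum()))
    kept = t[~(fail_call | fail_info | fail_maf)].reset_index(drop=True)
    report.n_kept = len(kept)
    from dataclasses import replace

    return replace(stats_in, table=kept), report


def compute_lambda_gc(z_or_p: np.ndarray, is_p: bool = False) -> float:
    """Genomic-control lambda: median chi-square over the null median.

    Accepts Z scores (default) or two-sided P values (``is_p=True``).
    """
    x = np.asarray(z_or_p, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("need at least 100 values for a stable lambda")
    chi2 = stats.chi2.isf(x, df=1) if is_p else x**2
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def estimate_ldsc_intercept(
    chi2: np.ndarray,
    ld_scores: np.ndarray,
    n: float | np.ndarray,
    m: int | None = None,
) -> tuple[float, float]:
    """Intercept of LD-score regression of chi-square on the LD score.

    One-step iterated weights 1 / (2 (1 + N h2 l / M)^2) from a first-pass
    unweighted fit.  Returns (intercept, slope-implied h2).  Refuses fewer
    than 200 SNPs (jackknife blocks would be unstable).
    """
    chi2 = np.asarray(chi2, dtype=float)
    ell = np.asarray(ld_scores, dtype=float)
    if chi2.size < 200:
        raise ValueError("need at least 200 SNPs for LD-score regression")
    n = np.broadcast_to(np.asarray(n, dtype=float), chi2.shape)
    m = m or chi2.size

    def _wls(w):
        X = np.column_stack([np.ones_like(ell), n * ell / m])
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], chi2 * W, rcond=None)
        return coef

    c0 = _wls(np.ones_like(chi2))
    h2_first = max(c0[1], 0.0)
    w = 1.0 / (2.0 * (1.0 + np.maximum(n * h2_first * ell / m, 0.0)) ** 2)
    coef = _wls(w)
    return float(coef[0]), float(coef[1])


@dataclass
class StudyResult:
    """Per-study summary statistics plus inflation diagnostics."""

    study_id: str
    stats: PopulationStats
    lambda_gc: float = np.nan
    ldsc_intercept: float = np.nan
    correction_applied: str = ""

    @property
    def n(self) -> int:
        return self.stats.n_total


def choose_correction_factor(
    study: StudyResult, n_threshold: int = 3000
) -> tuple[float, str, bool]:
    """Select the inflation-correction factor for one study.

    LD-score intercept for studies with N > 3000, genomic-control lambda
    otherwise; the chosen factor is floored at 1 (no deflation).  A study is
    flagged inflated when both diagnostics exceed 1.1.
    """
    if study.n > n_threshold:
        factor, label = study.ldsc_intercept, "ldsc_intercept"
    else:
        factor, label = study.lambda_gc, "lambda_gc"
    inflated = study.lambda_gc > 1.1 and study.ldsc_intercept > 1.1
    return max(float(factor), 1.0), label, inflated


def apply_correction(stats_in: PopulationStats, factor: float) -> PopulationStats:
    """Divide chi-square by the factor: SE inflated by sqrt(factor)."""
    from dataclasses import replace

    factor = max(factor, 1.0)
    t = stats_in.table.copy()
    t["SE"] = t["SE"] * np.sqrt(factor)
    z2 = (t["BETA"] / t["SE"]) ** 2
    t["P"] = np.exp(stats.chi2.logsf(z2, df=1))
    return replace(stats_in, table=t)


def ivw_meta(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effects inverse-variance-weighted pooling of one SNP.

    Returns (pooled beta, pooled SE, two-sided P).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    if not ok.any():
        raise ValueError("no study with finite SE")
    w = 1.0 / ses[ok] ** 2
    beta = float(np.sum(w * betas[ok]) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(np.exp(stats.chi2.logsf((beta / se) ** 2, df=1)))
    return beta, se, p


def cochran_q(betas: np.ndarray, ses: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test across k >= 2 studies.

    Q = sum w_i (beta_i - beta_pooled)^2 with w_i = 1/se_i^2; P from the
    upper tail of chi-square with k-1 df.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        raise ValueError("Cochran's Q needs >= 2 groups")
    w = 1.0 / ses**2
    pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = betas.size - 1
    p = float(np.exp(stats.chi2.logsf(q, df=df)))
    return q, df, p


@dataclass
class MetaResult:
    """Per-SNP pooled results across studies for one trait."""

    trait: str
    table: pd.DataFrame  # SNP, CHR, POS, BETA, SE, P, Q_HET, P_HET, N_EFF, K
    n_total: int = 0


def meta_analyze(
    studies: list[PopulationStats], trait: str | None = None
) -> MetaResult:
    """IVW meta-analysis over studies sharing a SNP universe (union).

    A SNP absent (or QC-failed) in a study simply does not contribute to that
    SNP's pooled estimate.  Heterogeneity Q/P are computed where k >= 2.
    """
    trait = trait or (studies[0].trait if studies else "")
    frames = []
    for i, s in enumerate(studies):
        f = s.table[["CHR", "POS", "SNP", "BETA", "SE", "N"]].copy()
        f["STUDY"] = i
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)

    rows = []
    for snp, grp in long.groupby("SNP", sort=False):
        betas = grp["BETA"].to_numpy()
        ses = grp["SE"].to_numpy()
        beta, se, p = ivw_meta(betas, ses)
        if len(grp) >= 2:
            q, _, p_het = cochran_q(betas, ses)
        else:
            q, p_het = 0.0, 1.0
        rows.append(
            {
                "CHR": grp["CHR"].iloc[0],
                "POS": grp["POS"].iloc[0],
                "SNP": snp,
                "BETA": beta,
                "SE": se,
                "P": p,
                "Q_HET": q,
                "P_HET": p_het,
                "N_EFF": int(grp["N"].sum()),
                "K": len(grp),
            }
        )
    table = pd.DataFrame(rows).sort_values(["CHR", "POS"]).reset_index(drop=True)
    n_total = int(sum(s.n_total for s in studies))
    return MetaResult(trait=trait, table=table, n_total=n_total)


def reporting_filter(
    meta: MetaResult, n_total: int | None = None, p_het_min: float = 1e-6
) -> MetaResult:
    """Keep SNPs with heterogeneity P > 1e-6 and N_eff >= half the total N."""
    n_total = n_total if n_total is not None else meta.n_total
    t = meta.table
    kept = t[(t["P_HET"] > p_het_min) & (t["N_EFF"] >= n_total / 2.0)]
    return MetaResult(meta.trait, kept.reset_index(drop=True), n_total)


def select_followup(
    per_trait: dict[str, MetaResult], p_threshold: float = FOLLOWUP_P
) -> set[str]:
    """Union over traits of SNPs with P below the follow-up threshold."""
    selected: set[str] = set()
    for meta in per_trait.values():
        t = meta.table
        selected.update(t.loc[t["P"] < p_threshold, "SNP"])
    return selected


@dataclass
class ValidationResult:
    validated: bool
    failed: list[str] = field(default_factory=list)


def validate_signal(
    p_combined: float,
    p_stage2: float,
    p_lookup: float,
    directions_concordant: bool,
    n_lookup_snps: int,
) -> ValidationResult:
    """Four-criterion validation of a sentinel SNP.

    (i) combined meta P < 5e-8; (ii) stage-2 P < 0.05; (iii) lookup
    P < 0.05 / n_lookup_snps; (iv) concordant effect directions throughout.
    """
    for name, val in (("p_combined", p_combined), ("p_stage2", p_stage2),
                      ("p_lookup", p_lookup)):
        if val is None or not np.isfinite(val):
            raise ValueError(f"validation criterion not evaluable: missing {name}")
    failed = []
    if not p_combined < GENOME_WIDE_P:
        failed.append("i_combined_significance")
    if not p_stage2 < 0.05:
        failed.append("ii_stage2_support")
    if not p_lookup < 0.05 / n_lookup_snps:
        failed.append("iii_lookup_support")
    if not directions_concordant:
        failed.append("iv_direction_concordance")
    return ValidationResult(validated=not failed, failed=failed)
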