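"""Blood-pressure phenotype modeling and per-SNP association testing.

Phenotype rules: individuals on antihypertensive treatment get +15 mmHg SBP
and +10 mmHg DBP imputed before quantitative-trait analysis; mean arterial
pressure is (2 DBP + SBP)/3 and pulse pressure SBP - DBP; hypertension
case/control status is derived from raw (unadjusted) readings plus the
treatment flag.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import PopulationStats, SUMSTAT_COLUMNS
from .simulate import Cohort

#: mmHg added to SBP / DBP for treated individuals
TREATMENT_SBP_OFFSET = 15.0
TREATMENT_DBP_OFFSET = 10.0


class HtClass(str, Enum):
    CASE = "case"
    CONTROL = "control"
    EXCLUDED = "excluded"


def adjust_for_treatment(sbp, dbp, treated):
    """Impute pre-treatment blood pressure: treated -> (SBP+15, DBP+10)."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    treated = np.asarray(treated, dtype=bool)
    return (
        sbp + TREATMENT_SBP_OFFSET * treated,
        dbp + TREATMENT_DBP_OFFSET * treated,
    )


def derive_map_pp(sbp, dbp):
    """MAP = (2 DBP + SBP)/3 and PP = SBP - DBP."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp < dbp):
        warnings.warn("SBP < DBP for some individuals; MAP/PP still computed")
    return (2.0 * dbp + sbp) / 3.0, sbp - dbp


def classify_hypertension(
    sbp: float,
    dbp: float,
    treated: bool,
    age: float,
    onset_age: float | None = None,
) -> HtClass:
    """Case/control/excluded classification from raw blood pressure.

    Case: (SBP >= 160 or DBP >= 100 or treated) and onset age <= 65.
    Control: SBP < 130 and DBP < 85 and untreated and age >= 50.
    Everyone else (including BP-qualifying cases with unknown onset age) is
    excluded.
    """
    bp_case = sbp >= 160.0 or dbp >= 100.0 or treated
    if bp_case:
        if onset_age is not None and not np.isnan(onset_age) and onset_age <= 65.0:
            return HtClass.CASE
        return HtClass.EXCLUDED
    if sbp < 130.0 and dbp < 85.0 and not treated and age >= 50.0:
        return HtClass.CONTROL
    return HtClass.EXCLUDED


def classify_cohort(pheno: pd.DataFrame) -> pd.Series:
    """Vector version of :func:`classify_hypertension` over a cohort frame."""
    onset = pheno.get("ONSET_AGE", pd.Series(np.nan, index=pheno.index))
    return pd.Series(
        [
            classify_hypertension(s, d, t, a, o)
            for s, d, t, a, o in zip(
                pheno["SBP"], pheno["DBP"], pheno["TREATED"], pheno["AGE"], onset
            )
        ],
        index=pheno.index,
        name="HT_CLASS",
    )


def _trait_vector(cohort: Cohort, trait: str, adjust_treatment: bool = True):
    pheno = cohort.phenotypes
    sbp, dbp = pheno["SBP"].to_numpy(), pheno["DBP"].to_numpy()
    if adjust_treatment:
        sbp, dbp = adjust_for_treatment(sbp, dbp, pheno["TREATED"].to_numpy())
    if trait == "SBP":
        return sbp, None
    if trait == "DBP":
        return dbp, None
    if trait in ("MAP", "PP"):
        m, p = derive_map_pp(sbp, dbp)
        return (m if trait == "MAP" else p), None
    if trait == "HT":
        cls = classify_cohort(pheno)
        y = np.where(cls == HtClass.CASE, 1.0, np.where(cls == HtClass.CONTROL, 0.0, np.nan))
        return y, ~np.isnan(y)
    raise ValueError(f"unknown trait {trait!r}")


def run_association(
    cohort: Cohort,
    trait: str = "SBP",
    covariates: pd.DataFrame | None = None,
    model: str = "linear",
    snp_ids: list[str] | None = None,
    population: str = "",
    resid_var: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> PopulationStats:
    """Single-SNP regression of a trait on allele dose, per SNP.

    Linear traits are fitted by OLS with an intercept and any covariates;
    hypertension by logistic regression (IRLS, ``tol`` convergence, at most
    ``max_iter`` iterations).  Monomorphic SNPs are skipped; logistic fits
    with separation are omitted.  ``resid_var``, when given, is treated as the
    known residual variance for SE computation instead of the OLS estimate
    (useful when the generating noise variance is known).
    """
    g_all = cohort.genotypes
    n_ind, m = g_all.shape
    y, keep = _trait_vector(cohort, trait)
    if model == "logistic" and trait != "HT":
        raise ValueError("logistic model is for the HT trait")
    if keep is None:
        keep = np.ones(n_ind, dtype=bool)
    y = y[keep]
    g_all = g_all[keep]
    cov = None
    if covariates is not None:
        if covariates.isna().any().any():
            raise ValueError("missing covariate values are not supported")
        cov = covariates.to_numpy(dtype=float)[keep]

    meta = cohort.snp_meta if len(cohort.snp_meta) else None
    rows = []
    for j in range(m):
        g = g_all[:, j].astype(float)
        eaf = g.mean() / 2.0
        if len(np.unique(g)) < 2:
            continue  # monomorphic
        X = np.column_stack([np.ones_like(g), g] if cov is None else
                            [np.ones_like(g), g, cov])
        if model == "linear":
            fit = sm.OLS(y, X).fit()
            beta, se = fit.params[1], fit.bse[1]
            if resid_var is not None:
                xtx_inv = np.linalg.inv(X.T @ X)
                se = float(np.sqrt(resid_var * xtx_inv[1, 1]))
            z = beta / se
            p = float(sps.chi2.sf(z * z, df=1))
        else:
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=max_iter, tol=tol)
            except Exception:
                continue
            if not fit.mle_retvals.get("converged", True) or np.any(
                np.abs(fit.params) > 30
            ):
                continue  # separation / non-convergence
            beta, se = fit.params[1], fit.bse[1]
            p = float(sps.chi2.sf((beta / se) ** 2, df=1))
        snp = (
            meta.iloc[j] if meta is not None
            else {"CHR": "1", "POS": j + 1, "SNP": f"snp{j}", "REF": "A", "ALT": "G"}
        )
        rows.append(
            {
                "CHR": str(snp["CHR"]),
                "POS": int(snp["POS"]),
                "SNP": str(snp["SNP"]),
                "EA": str(snp.get("ALT", "G")),
                "NEA": str(snp.get("REF", "A")),
                "EAF": eaf,
                "BETA": float(beta),
                "SE": float(se),
                "P": p,
                "N": int(len(y)),
                "INFO": 1.0,
                "CALL_RATE": 1.0,
            }
        )
    table = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)
    if snp_ids is not None:
        table = table[table["SNP"].isin(snp_ids)]
    return PopulationStats(population=population, trait=trait, table=table)
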