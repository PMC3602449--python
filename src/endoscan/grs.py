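"""Genetic risk score: counted risk genotypes over the top SNPs.

The risk side of each SNP's dominant dichotomy comes from the sign of
its adjusted effect — carriers are the risk group when carrying the
minor allele accelerates decline (negative beta), the reference
homozygotes otherwise.  A subject's score is the number of SNPs at
which they sit on the risk side; missing genotypes contribute zero, so
the score is a lower bound and subjects missing too many of the coded
SNPs are excluded from trend models.

Deriving the coding from the same scan whose top SNPs feed the score is
circular by construction (winner's curse); the trend P from the same
cohort overstates out-of-sample evidence and is reported as an in-
sample summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import ADJUSTMENT_COVARIATES, align_cohort, encode_genotype
from .io_formats import CovariateTable, GenotypePanel

CARRIER = "carrier"
NONCARRIER = "noncarrier"


@dataclass(frozen=True)
class TrendResult:
    beta: float   # ml/month per risk genotype
    se: float
    p: float
    n: int


def derive_risk_coding(results: pd.DataFrame) -> dict[str, str]:
    """Map each dominant-model SNP to its risk side by effect sign."""
    coding: dict[str, str] = {}
    for _, row in results.iterrows():
        beta = row["beta"]
        if not np.isfinite(beta):
            raise ValueError(f"SNP {row['snp_id']} has no finite beta")
        if beta == 0:
            raise ValueError(f"SNP {row['snp_id']}: zero beta, risk side undefined")
        coding[row["snp_id"]] = CARRIER if beta < 0 else NONCARRIER
    return coding


def compute_grs(panel: GenotypePanel, coding: dict[str, str]) -> pd.DataFrame:
    """Per-subject risk-genotype count.

    Returns a frame (subject, grs, n_missing, n_coded); missing calls
    add nothing to the score and are tallied separately.
    """
    k = len(coding)
    score = np.zeros(panel.n_subjects, dtype=int)
    n_missing = np.zeros(panel.n_subjects, dtype=int)
    for sid, side in coding.items():
        j = panel.snp_index(sid)
        code, _ = encode_genotype(panel.calls[:, j], "dominant")
        miss = np.isnan(code)
        if side == CARRIER:
            risk = (code == 1)
        elif side == NONCARRIER:
            risk = (code == 0)
        else:
            raise ValueError(f"bad risk side {side!r} for {sid}")
        score += np.where(miss, False, risk).astype(int)
        n_missing += miss.astype(int)
    return pd.DataFrame({"subject": panel.subjects, "grs": score,
                         "n_missing": n_missing, "n_coded": k})


def _aligned_grs(panel, slopes, cov, grs_df, max_missing_frac=0.2,
                 drop_covariate=None, endotoxin_order="log_of_mean"):
    idx, y, C_full = align_cohort(panel, slopes, cov,
                                  endotoxin_order=endotoxin_order)
    subjects = [panel.subjects[t] for t in idx]
    g = grs_df.set_index("subject").loc[subjects]
    keep = (g["n_missing"] / g["n_coded"] <= max_missing_frac).to_numpy()
    names = list(ADJUSTMENT_COVARIATES)
    if drop_covariate is not None:
        cols = [t for t, nm in enumerate(names) if nm != drop_covariate]
        C_full = C_full[:, cols]
    return (np.array(subjects)[keep], y[keep],
            g["grs"].to_numpy(dtype=float)[keep], C_full[keep])


def grs_trend(panel: GenotypePanel, slopes: pd.DataFrame, cov: CovariateTable,
              grs_df: pd.DataFrame, max_missing_frac: float = 0.2,
              drop_covariate: str | None = None) -> TrendResult:
    """Adjusted OLS of the slope on the score as one ordinal term."""
    _, y, g, C = _aligned_grs(panel, slopes, cov, grs_df,
                              max_missing_frac, drop_covariate)
    if np.ptp(g) == 0:
        raise ValueError("constant genetic risk score; trend undefined")
    X = np.column_stack([np.ones(len(y)), g, C])
    fit = sm.OLS(y, X).fit()
    return TrendResult(beta=float(fit.params[1]), se=float(fit.bse[1]),
                       p=float(fit.pvalues[1]), n=len(y))


def grs_category_effects(panel: GenotypePanel, slopes: pd.DataFrame,
                         cov: CovariateTable, grs_df: pd.DataFrame,
                         max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Per-score-category coefficients vs the lowest observed score —
    the coefficient-plot parameterization (unpooled categories)."""
    _, y, g, C = _aligned_grs(panel, slopes, cov, grs_df, max_missing_frac)
    levels = np.unique(g)
    D = np.column_stack([(g == lv).astype(float) for lv in levels[1:]])
    X = np.column_stack([np.ones(len(y)), C, D])
    fit = sm.OLS(y, X).fit()
    off = 1 + C.shape[1]
    rows = [{"grs": float(levels[0]), "n": int((g == levels[0]).sum()),
             "beta": 0.0, "se": np.nan, "ci_lo": np.nan, "ci_hi": np.nan}]
    ci = fit.conf_int()
    for t, lv in enumerate(levels[1:]):
        j = off + t
        rows.append({"grs": float(lv), "n": int((g == lv).sum()),
                     "beta": float(fit.params[j]), "se": float(fit.bse[j]),
                     "ci_lo": float(ci[j][0]), "ci_hi": float(ci[j][1])})
    return pd.DataFrame(rows)


def grs_stratified(panel: GenotypePanel, slopes: pd.DataFrame,
                   cov: CovariateTable, grs_df: pd.DataFrame,
                   strata: pd.Series, drop_covariate: str | None = None,
                   max_missing_frac: float = 0.2,
                   levels: list | None = None) -> dict:
    """Per-stratum trend plus the score×stratum interaction P.

    ``strata`` maps subject id to a stratum label (e.g. age band or
    endotoxin half); the stratifying covariate should be named in
    ``drop_covariate`` so it leaves the adjustment set.  Strata with
    too few subjects are flagged and get no trend estimate.  With a
    single stratum the pooled trend is returned and interaction_p is
    NaN.
    """
    subjects, y, g, C = _aligned_grs(panel, slopes, cov, grs_df,
                                     max_missing_frac, drop_covariate)
    lab = pd.Categorical(strata.loc[subjects], categories=levels, ordered=True)
    ok = ~np.asarray(lab.isna())
    y, g, C, lab = y[ok], g[ok], C[ok], lab[ok]
    lv = [l for l in lab.categories if (np.asarray(lab) == l).sum() > 0]

    per_stratum = {}
    k_par = C.shape[1] + 2
    for l in lv:
        m = np.asarray(lab) == l
        if m.sum() < k_par + 1 or np.ptp(g[m]) == 0:
            per_stratum[l] = {"n": int(m.sum()), "flagged": True,
                              "beta": np.nan, "se": np.nan, "p": np.nan}
            continue
        X = np.column_stack([np.ones(m.sum()), g[m], C[m]])
        fit = sm.OLS(y[m], X).fit()
        per_stratum[l] = {"n": int(m.sum()), "flagged": False,
                          "beta": float(fit.params[1]),
                          "se": float(fit.bse[1]), "p": float(fit.pvalues[1])}

    if len(lv) < 2:
        return {"per_stratum": per_stratum, "interaction_p": np.nan}

    codes = np.asarray(pd.Categorical(lab, categories=lv).codes)
    D = np.column_stack([(codes == t).astype(float) for t in range(1, len(lv))])
    base = np.column_stack([np.ones(len(y)), C, g, D])
    full = np.column_stack([base, D * g[:, None]])
    fit_full = sm.OLS(y, full).fit()
    fit_red = sm.OLS(y, base).fit()
    _, fp, _ = fit_full.compare_f_test(fit_red)
    n_prod = len(lv) - 1
    return {"per_stratum": per_stratum, "interaction_p": float(fp),
            "interaction_betas": [float(b) for b in fit_full.params[-n_prod:]]}


# --------------------------------------------------------------------------
# stratum constructors
# --------------------------------------------------------------------------

AGE_BAND_LEVELS = ["<18", "18-25", ">=25"]


def age_bands(cov: CovariateTable) -> pd.Series:
    """Age strata <18, [18, 25), >=25 years (25 goes to the upper band)."""
    age = cov.subjects.set_index("subject")["age"]
    out = pd.Series(np.select([age < 18, age < 25], AGE_BAND_LEVELS[:2],
                              AGE_BAND_LEVELS[2]),
                    index=age.index, name="age_band")
    return out


ENDOTOXIN_LEVELS = ["low", "high"]


def endotoxin_strata(cov: CovariateTable, median: float | None = None
                     ) -> pd.Series:
    """Dichotomize mean exposure at the cohort median; ties go low."""
    mean_exposure = cov.endotoxin.groupby("subject")["endotoxin"].mean()
    med = float(mean_exposure.median()) if median is None else median
    out = pd.Series(np.where(mean_exposure <= med, "low", "high"),
                    index=mean_exposure.index, name="endotoxin_stratum")
    return out
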