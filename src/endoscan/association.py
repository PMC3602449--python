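"""Per-SNP covariate-adjusted linear models for the slope phenotype.

Each SNP is recoded under a dominant (carrier of the minor allele
yes/no) or additive (minor-allele count) model and entered into an OLS
regression of the per-subject FEV1 slope on genotype plus the standard
adjustment set: height, age, baseline FEV1 and the log of the mean
endotoxin exposure.  The sign convention follows the carrier contrast:
a negative beta means carriers decline faster.

Under the additive model, SNPs whose rare-homozygote frequency is at or
below 5% of non-missing calls are excluded for lack of robustness;
monomorphic SNPs are excluded under either model.

The scan uses a Frisch–Waugh–Lovell projection shared across SNPs —
residualize genotype and phenotype on the covariates once, then each
SNP coefficient is a one-dimensional regression.  This is numerically
identical to the per-SNP full fit (tested against it) and is what makes
permutation re-scans affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, CovariateTable, GenotypePanel

DOMINANT = "dominant"
ADDITIVE = "additive"
ADJUSTMENT_COVARIATES = ("height", "age", "fev1_baseline", "log_endotoxin")


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    model: str
    n_ref: int
    n_carrier: int
    mean_ref: float
    sd_ref: float
    mean_carrier: float
    sd_carrier: float
    beta: float
    se: float
    p: float
    excluded: bool = False
    reason: str = ""


@dataclass(frozen=True)
class ScanSummary:
    lambda_gc: float
    n_tested: int
    n_excluded: int


# --------------------------------------------------------------------------
# genotype encoding
# --------------------------------------------------------------------------

def encode_genotype(calls: np.ndarray, model: str
                    ) -> tuple[np.ndarray, str | None]:
    """Numeric genotype code (NaN for missing) plus an exclusion reason.

    Codes count the *minor* allele: dominant gives 0 for major-allele
    homozygotes and 1 for any minor-allele carrier; additive gives the
    minor-allele count 0/1/2.
    """
    if model not in (DOMINANT, ADDITIVE):
        raise ValueError(f"unknown genetic model {model!r}")
    calls = np.asarray(calls)
    obs = calls != MISSING
    n = int(obs.sum())
    if n == 0:
        return np.full(calls.shape, np.nan), "all_missing"
    freq_b = (calls[obs] == 1).sum() / (2.0 * n) + (calls[obs] == 2).sum() / n
    minor_count = np.where(calls == MISSING, -1,
                           calls if freq_b <= 0.5 else 2 - calls)
    code = minor_count.astype(float)
    code[~obs] = np.nan
    if model == DOMINANT:
        code = np.where(np.isnan(code), np.nan, (code >= 1).astype(float))
    uniq = np.unique(code[obs])
    if len(uniq) < 2:
        return code, "monomorphic"
    if model == ADDITIVE:
        rare_hom_freq = (minor_count == 2).sum() / n
        if rare_hom_freq <= 0.05:
            return code, "rare_homozygote"
    return code, None


# --------------------------------------------------------------------------
# OLS core
# --------------------------------------------------------------------------

def _ols_fit(y: np.ndarray, X: np.ndarray):
    """Least-squares fit; returns (beta, se, df) or None if rank-deficient."""
    n, k = X.shape
    if n <= k:
        return None
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        return None
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return beta, se, df


def _group_summary(es: np.ndarray, code: np.ndarray) -> tuple:
    ref = es[code == 0]
    car = es[code > 0]

    def _ms(v):
        if len(v) == 0:
            return np.nan, np.nan
        return float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else np.nan

    mr, sr = _ms(ref)
    mc, sc = _ms(car)
    return len(ref), len(car), mr, sr, mc, sc


def fit_snp_model(es: np.ndarray, code: np.ndarray, covariates: np.ndarray,
                  snp_id: str = "", model: str = DOMINANT) -> AssociationResult:
    """OLS of the slope phenotype on [intercept, genotype, covariates].

    Complete cases only; beta/se/p refer to the genotype coefficient
    (two-sided t test).  Unadjusted per-group mean and SD of the slope
    are reported alongside.
    """
    es = np.asarray(es, dtype=float)
    code = np.asarray(code, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = ~(np.isnan(es) | np.isnan(code) | np.isnan(C).any(axis=1))
    es, code, C = es[ok], code[ok], C[ok]
    n_ref, n_car, mr, sr, mc, sc = _group_summary(es, code)

    def _excluded(reason):
        return AssociationResult(snp_id, model, n_ref, n_car, mr, sr, mc, sc,
                                 np.nan, np.nan, np.nan, True, reason)

    k_cov = C.shape[1]
    if len(es) <= k_cov + 2:
        return _excluded("too_few_complete_cases")
    X = np.column_stack([np.ones(len(es)), code, C])
    fit = _ols_fit(es, X)
    if fit is None:
        return _excluded("rank_deficient")
    beta, se, df = fit
    with np.errstate(divide="ignore"):
        t = np.inf if se[1] == 0 else beta[1] / se[1]
    # exact (zero-residual) fits underflow to 0; keep P in (0, 1]
    p = max(2.0 * stats.t.sf(abs(t), df), np.finfo(float).tiny)
    return AssociationResult(snp_id, model, n_ref, n_car, mr, sr, mc, sc,
                             float(beta[1]), float(se[1]), float(p))


# --------------------------------------------------------------------------
# cohort alignment and the scan
# --------------------------------------------------------------------------

def align_cohort(panel: GenotypePanel, slopes: pd.DataFrame,
                 cov: CovariateTable, endotoxin_order: str = "log_of_mean",
                 min_age: float | None = None,
                 pcs: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersect subjects across panel/slopes/covariates (panel order).

    Returns (subject indices into the panel, es vector, covariate
    matrix).  ``pcs`` appends per-subject principal-component columns
    (aligned with panel subject order) as sensitivity covariates.
    """
    es_by_subject = slopes.set_index("subject")["es"]
    design = cov.design_frame(endotoxin_order=endotoxin_order)
    if min_age is not None:
        design = design[design["age"] >= min_age]
    common = [s for s in panel.subjects
              if s in es_by_subject.index and s in design.index]
    if not common:
        raise ValueError("no subjects shared by panel, slopes and covariates")
    idx = np.array([panel.subjects.index(s) for s in common])
    y = es_by_subject.loc[common].to_numpy(dtype=float)
    C = design.loc[common, list(ADJUSTMENT_COVARIATES)].to_numpy(dtype=float)
    if pcs is not None:
        C = np.column_stack([C, np.asarray(pcs)[idx]])
    return idx, y, C


def scan(panel: GenotypePanel, slopes: pd.DataFrame, cov: CovariateTable,
         model: str = DOMINANT, endotoxin_order: str = "log_of_mean",
         min_age: float | None = None, pcs: np.ndarray | None = None
         ) -> tuple[pd.DataFrame, ScanSummary]:
    """Covariate-adjusted association of every SNP with the slope."""
    idx, y, C = align_cohort(panel, slopes, cov,
                             endotoxin_order=endotoxin_order,
                             min_age=min_age, pcs=pcs)
    calls = panel.calls[idx]
    n, k_cov = len(y), C.shape[1]
    Xc = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(Xc)

    codes = np.empty((n, panel.n_snps))
    reasons: list[str | None] = []
    for j in range(panel.n_snps):
        cj, reason = encode_genotype(calls[:, j], model)
        codes[:, j] = cj
        reasons.append(reason)
    complete = ~np.isnan(codes).any(axis=0)
    fast = complete & np.array([r is None for r in reasons])

    beta = np.full(panel.n_snps, np.nan)
    se = np.full(panel.n_snps, np.nan)
    pvals = np.full(panel.n_snps, np.nan)
    excluded = np.array([r is not None for r in reasons])

    if fast.any():
        G = codes[:, fast]
        Gt = G - Q @ (Q.T @ G)
        yt = y - Q @ (Q.T @ y)
        sg = (Gt ** 2).sum(axis=0)
        df = n - k_cov - 2
        ok = sg > max(1e-10, n) * np.finfo(float).eps
        num = Gt.T @ y
        b = np.where(ok, num / np.where(ok, sg, 1.0), np.nan)
        ssr = yt @ yt - b ** 2 * sg
        s = np.sqrt(np.clip(ssr, 0.0, None) / df / np.where(ok, sg, np.nan))
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = b / s
        tstat = np.where((s == 0) & np.isfinite(b), np.inf, tstat)
        pv = np.maximum(2.0 * stats.t.sf(np.abs(tstat), df), np.finfo(float).tiny)
        beta[fast], se[fast], pvals[fast] = b, s, pv
        fast_idx = np.flatnonzero(fast)
        bad = fast_idx[~ok]
        excluded[bad] = True
        for jj in bad:
            reasons[jj] = "rank_deficient"

    rows = []
    for j in range(panel.n_snps):
        snp_id = panel.snps[j].snp_id
        if fast[j] and not excluded[j]:
            n_ref, n_car, mr, sr, mc, sc = _group_summary(y, codes[:, j])
            rows.append(AssociationResult(snp_id, model, n_ref, n_car, mr, sr,
                                          mc, sc, beta[j], se[j], pvals[j]))
        elif excluded[j]:
            obs = ~np.isnan(codes[:, j])
            n_ref, n_car, mr, sr, mc, sc = _group_summary(y[obs], codes[obs, j])
            rows.append(AssociationResult(snp_id, model, n_ref, n_car, mr, sr,
                                          mc, sc, np.nan, np.nan, np.nan,
                                          True, reasons[j] or "rank_deficient"))
        else:
            # per-SNP complete-case fit (missing genotype calls present)
            rows.append(fit_snp_model(y, codes[:, j], C, snp_id=snp_id,
                                      model=model))

    df_rows = pd.DataFrame([r.__dict__ for r in rows])
    tested = df_rows[~df_rows["excluded"]]
    lam = genomic_control_lambda(tested["p"].to_numpy()) if len(tested) else np.nan
    summary = ScanSummary(lambda_gc=lam, n_tested=len(tested),
                          n_excluded=int(df_rows["excluded"].sum()))
    return df_rows, summary


CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


def genomic_control_lambda(pvalues: np.ndarray) -> float:
    """Median association chi-square over the null median (1 df)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def manhattan_export(panel: GenotypePanel, results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready per-SNP frame: chromosome, position, -log10 P."""
    meta = pd.DataFrame({
        "snp_id": panel.snp_ids,
        "chromosome": [s.chromosome for s in panel.snps],
        "position": [s.position for s in panel.snps],
    })
    out = meta.merge(results[["snp_id", "p"]], on="snp_id", how="inner")
    out["neg_log10_p"] = -np.log10(out["p"])
    return out
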