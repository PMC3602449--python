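"""Study-wide error control by permutation, plus Benjamini–Hochberg.

The scan's P-values are correlated through linkage disequilibrium, so a
Bonferroni divisor overcounts the effective number of tests.  The
calibration here permutes the *phenotype* while leaving genotype
columns intact, preserving inter-SNP correlation: each permutation
replicate re-runs the full scan on a null phenotype and records every
null P-value and their minimum.

The null phenotype follows the Freedman–Lane scheme by default: the
slope is first regressed on the adjustment covariates, the residuals
are permuted across subjects, and the fitted covariate part is added
back — so the null respects the covariate structure of the association
model.  A raw-shuffle scheme is available behind a flag.

From the replicate record:

* the FWER-controlling per-test threshold is the alpha-quantile of the
  min-P distribution;
* permutation FDR q-values compare, at each observed P, the average
  count of null P-values at or below it against the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import align_cohort, encode_genotype
from .io_formats import CovariateTable, GenotypePanel


@dataclass
class PermutationNull:
    """Null P-values from phenotype-permutation replicates."""

    n_perm: int
    seed: int
    scheme: str
    minp: np.ndarray          # (n_perm,) per-replicate minimum P
    null_p_sorted: np.ndarray  # sorted pool of all null P (n_perm * m)
    n_snps: int


def build_permutation_null(panel: GenotypePanel, slopes: pd.DataFrame,
                           cov: CovariateTable, model: str = "dominant",
                           n_perm: int = 1000, seed: int = 0,
                           scheme: str = "freedman_lane",
                           endotoxin_order: str = "log_of_mean"
                           ) -> PermutationNull:
    """Re-scan ``n_perm`` permuted phenotypes and record all null P.

    Genotype columns are never permuted independently of one another,
    so the linkage structure of the panel carries into the null.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable tail quantiles")
    if scheme not in ("freedman_lane", "raw"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    idx, y, C = align_cohort(panel, slopes, cov,
                             endotoxin_order=endotoxin_order)
    calls = panel.calls[idx]
    n, k_cov = len(y), C.shape[1]
    Xc = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(Xc)

    codes = []
    for j in range(panel.n_snps):
        cj, reason = encode_genotype(calls[:, j], model)
        if reason is None:
            codes.append(cj)
    if not codes:
        raise ValueError("no testable SNPs in panel")
    G = np.column_stack(codes)
    m = G.shape[1]

    rng = np.random.default_rng(seed)
    if scheme == "freedman_lane":
        base = y - Q @ (Q.T @ y)  # covariate-adjusted residuals
    else:
        base = y
    # permuted phenotype columns; adding back fitted values is a no-op
    # for the genotype t statistic (the projection removes them again)
    E = np.empty((n, n_perm))
    for b in range(n_perm):
        E[:, b] = base[rng.permutation(n)]

    if np.isnan(G).any():
        # per-SNP complete cases: fall back to column-wise projection
        pnull = np.empty((m, n_perm))
        for j in range(m):
            g = G[:, j]
            ok = ~np.isnan(g)
            Qj, _ = np.linalg.qr(Xc[ok])
            gt = g[ok] - Qj @ (Qj.T @ g[ok])
            sg = float(gt @ gt)
            Ej = E[ok]
            A = Qj.T @ Ej
            ssr_y = (Ej ** 2).sum(axis=0) - (A ** 2).sum(axis=0)
            num = gt @ Ej
            dfj = ok.sum() - k_cov - 2
            pnull[j] = _t_pvalues(num, sg, ssr_y, dfj)
    else:
        Gt = G - Q @ (Q.T @ G)
        sg = (Gt ** 2).sum(axis=0)
        A = Q.T @ E
        ssr_y = (E ** 2).sum(axis=0) - (A ** 2).sum(axis=0)
        num = Gt.T @ E                       # (m, n_perm)
        df = n - k_cov - 2
        pnull = _t_pvalues(num, sg[:, None], ssr_y[None, :], df)

    minp = pnull.min(axis=0)
    return PermutationNull(n_perm=n_perm, seed=seed, scheme=scheme,
                           minp=minp, null_p_sorted=np.sort(pnull, axis=None),
                           n_snps=m)


def _t_pvalues(num, sg, ssr_y, df):
    """Two-sided t-test P for the FWL one-dimensional regression."""
    beta = num / sg
    ssr_full = ssr_y - num ** 2 / sg
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta * np.sqrt(sg * df / np.clip(ssr_full, 1e-300, None))
    return np.maximum(2.0 * stats.t.sf(np.abs(tstat), df), np.finfo(float).tiny)


def fwer_threshold(null: PermutationNull, alpha: float) -> float:
    """Per-test P threshold controlling family-wise error at ``alpha``:
    the lower-tail alpha-quantile of the min-P distribution."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    return float(np.quantile(null.minp, alpha, method="inverted_cdf"))


def permutation_fdr(observed_p: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Permutation q-values: expected null exceedances over observed.

    q(p) = (average per-replicate count of null P <= p) / #{observed
    P <= p}, capped at 1 and made monotone non-decreasing in p.
    """
    p = np.asarray(observed_p, dtype=float)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    null_counts = np.searchsorted(null.null_p_sorted, sorted_p, side="right")
    expected_false = null_counts / null.n_perm
    # ties: every index in a tie block shares the block's full count
    observed_counts = np.searchsorted(sorted_p, sorted_p, side="right")
    q_sorted = np.minimum(expected_false / observed_counts, 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Classical per-test level alpha / m (shown for comparison with the
    permutation threshold, which is less conservative under LD)."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests
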