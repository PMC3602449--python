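"""Bootstrap internal validation of individual SNP hits.

A hit is called *stable* when, across subject-level bootstrap
resamples, its association P stays at or below a predefined threshold
in at least 80% of replicates.  The threshold defaults to a Bonferroni
share of 0.05 over the SNPs under validation (0.005 when validating 10
SNPs).  Replicates in which the resampled genotype column is constant,
or the design is otherwise degenerate, count as non-significant —
redrawing them would bias the proportion upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import encode_genotype, align_cohort
from .io_formats import CovariateTable, GenotypePanel
from .slopes import estimate_slope

STABILITY_CUTOFF = 0.80


@dataclass(frozen=True)
class StabilityResult:
    snp_id: str
    n_boot: int
    p_threshold: float
    n_significant: int
    proportion: float
    stable: bool
    seed: int


def default_p_threshold(n_snps_validated: int, alpha: float = 0.05) -> float:
    return alpha / n_snps_validated


def bootstrap_stability(panel: GenotypePanel, slopes: pd.DataFrame,
                        cov: CovariateTable, snp_id: str,
                        model: str = "dominant", n_boot: int = 2000,
                        p_threshold: float = 0.005, seed: int = 0,
                        pheno=None) -> StabilityResult:
    """Resample subjects with replacement and refit one SNP's model.

    Subjects are the resampling unit; their covariates (and optionally
    their raw visit records, when ``pheno`` is given and slopes are to
    be re-estimated per replicate) travel with them.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    j = panel.snp_index(snp_id)
    idx, y, C = align_cohort(panel, slopes, cov)
    code, reason = encode_genotype(panel.calls[idx, j], model)
    if reason is not None:
        raise ValueError(f"SNP {snp_id} not testable: {reason}")
    ok = ~(np.isnan(code) | np.isnan(y) | np.isnan(C).any(axis=1))
    code, y, C = code[ok], y[ok], C[ok]
    n = len(y)
    k = C.shape[1] + 2

    visit_groups = None
    if pheno is not None:
        kept = [panel.subjects[t] for t in idx[ok]]
        recs = pheno.records
        visit_groups = [recs[recs["subject"] == s] for s in kept]

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_boot):
        take = rng.integers(0, n, n)
        g = code[take]
        if len(np.unique(g)) < 2:
            continue  # degenerate replicate counts as non-significant
        if visit_groups is None:
            yb = y[take]
        else:
            yb = np.empty(n)
            for t, src in enumerate(take):
                grp = visit_groups[src]
                yb[t] = estimate_slope(grp["month"].to_numpy(),
                                       grp["fev1"].to_numpy()).es
        X = np.column_stack([np.ones(n), g, C[take]])
        beta, _, rank, _ = np.linalg.lstsq(X, yb, rcond=None)
        if rank < X.shape[1]:
            continue
        resid = yb - X @ beta
        df = n - X.shape[1]
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(max(xtx_inv[1, 1] * sigma2, 0.0))
        if se == 0:
            continue
        p = 2.0 * stats.t.sf(abs(beta[1] / se), df)
        if p <= p_threshold:
            hits += 1
    prop = hits / n_boot
    return StabilityResult(snp_id=snp_id, n_boot=n_boot,
                           p_threshold=p_threshold, n_significant=hits,
                           proportion=prop, stable=prop >= STABILITY_CUTOFF,
                           seed=seed)
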