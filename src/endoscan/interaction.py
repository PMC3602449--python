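"""Gene–gene and gene–environment interaction models.

Two parameterizations of the same linear model are fitted for each
pair.  The *product* model adds a single A×B term to the main effects
and reads the interaction off its t test; the *joint-cell* model codes
every (level_a, level_b) combination against the double-reference cell
and yields the per-cell contrasts reported in study tables.  The two
are linear reparameterizations with identical fitted values.

For a multi-level environment the interaction is an F test comparing
the full joint model against mains-only; with a two-level environment
this F equals the squared product-term t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import align_cohort, encode_genotype
from .io_formats import CovariateTable, GenotypePanel
from .multiplicity import bh_fdr


@dataclass
class InteractionCell:
    level_a: object
    level_b: object
    n: int
    mean: float
    sd: float
    beta: float   # NaN for the reference cell and for empty cells
    se: float
    p: float
    reference: bool = False


@dataclass
class InteractionResult:
    factor_a: str
    factor_b: str
    cells: list[InteractionCell]
    interaction_p: float
    q: float = np.nan
    product_beta: float = np.nan  # A*B coefficient (gene-gene only)
    product_se: float = np.nan

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.cells])


def _cell_stats(es, mask):
    v = es[mask]
    if len(v) == 0:
        return 0, np.nan, np.nan
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
    return int(len(v)), float(np.mean(v)), sd


def fit_gene_gene(es, code_a, code_b, cov, name_a: str = "A", name_b: str = "B"
                  ) -> InteractionResult:
    """Interaction of two dominant-coded SNPs on the slope phenotype.

    Returns the 2×2 joint-cell table (reference = double noncarrier)
    and the product-term interaction P from the mains+product model.
    """
    es = np.asarray(es, dtype=float)
    A = np.asarray(code_a, dtype=float)
    B = np.asarray(code_b, dtype=float)
    C = np.asarray(cov, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = (~np.isnan(es) & ~np.isnan(A) & ~np.isnan(B)
          & ~np.isnan(C).any(axis=1))
    es, A, B, C = es[ok], A[ok], B[ok], C[ok]

    # product parameterization
    Xp = np.column_stack([np.ones(len(es)), C, A, B, A * B])
    interaction_p = product_beta = product_se = np.nan
    if np.linalg.matrix_rank(Xp) == Xp.shape[1]:
        fit = sm.OLS(es, Xp).fit()
        interaction_p = float(fit.pvalues[-1])
        product_beta = float(fit.params[-1])
        product_se = float(fit.bse[-1])

    # joint-cell parameterization
    cell_levels = [(0, 0), (0, 1), (1, 0), (1, 1)]
    masks = {(a, b): (A == a) & (B == b) for a, b in cell_levels}
    any_empty = any(m.sum() == 0 for m in masks.values())
    cells: list[InteractionCell] = []
    if not any_empty:
        D = np.column_stack([masks[lv].astype(float) for lv in cell_levels[1:]])
        Xc = np.column_stack([np.ones(len(es)), C, D])
        fit_c = sm.OLS(es, Xc).fit()
        off = 1 + C.shape[1]
        for t, lv in enumerate(cell_levels):
            n, mean, sd = _cell_stats(es, masks[lv])
            if t == 0:
                cells.append(InteractionCell(lv[0], lv[1], n, mean, sd,
                                             np.nan, np.nan, np.nan, True))
            else:
                cells.append(InteractionCell(
                    lv[0], lv[1], n, mean, sd,
                    float(fit_c.params[off + t - 1]),
                    float(fit_c.bse[off + t - 1]),
                    float(fit_c.pvalues[off + t - 1])))
    else:
        for t, lv in enumerate(cell_levels):
            n, mean, sd = _cell_stats(es, masks[lv])
            cells.append(InteractionCell(lv[0], lv[1], n, mean, sd,
                                         np.nan, np.nan, np.nan, t == 0))
    return InteractionResult(factor_a=name_a, factor_b=name_b, cells=cells,
                             interaction_p=interaction_p,
                             product_beta=product_beta, product_se=product_se)


def fit_gene_environment(es, code, env_levels, cov, name_a: str = "SNP",
                         name_b: str = "env", levels: list | None = None
                         ) -> InteractionResult:
    """Dominant genotype × categorical environment joint-cell model.

    ``env_levels`` is a per-subject label array; ``levels`` fixes the
    level order (first level + noncarrier is the reference cell).  The
    interaction P is an F test of the genotype×environment products on
    (L-1) numerator degrees of freedom.  Any environment-derived
    covariate must already be absent from ``cov``.
    """
    es = np.asarray(es, dtype=float)
    A = np.asarray(code, dtype=float)
    env = pd.Categorical(env_levels, categories=levels, ordered=True)
    C = np.asarray(cov, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = (~np.isnan(es) & ~np.isnan(A) & ~np.asarray(env.isna())
          & ~np.isnan(C).any(axis=1))
    es, A, C = es[ok], A[ok], C[ok]
    env = env[ok]
    lv = list(env.categories)
    if len(lv) < 2:
        raise ValueError("environment must have >= 2 levels")
    env_codes = env.codes

    env_dummies = np.column_stack([(env_codes == t).astype(float)
                                   for t in range(1, len(lv))])
    inter = env_dummies * A[:, None]
    base = np.column_stack([np.ones(len(es)), C, A, env_dummies])
    full = np.column_stack([base, inter])

    interaction_p = np.nan
    if np.linalg.matrix_rank(full) == full.shape[1]:
        fit_full = sm.OLS(es, full).fit()
        fit_red = sm.OLS(es, base).fit()
        fstat, fp, _ = fit_full.compare_f_test(fit_red)
        interaction_p = float(fp)

    # joint-cell table over genotype x environment
    cell_levels = [(a, l) for a in (0, 1) for l in lv]
    masks = {(a, l): (A == a) & (np.asarray(env) == l) for a, l in cell_levels}
    ordered = [(0, lv[0])] + [c for c in cell_levels if c != (0, lv[0])]
    any_empty = any(m.sum() == 0 for m in masks.values())
    cells: list[InteractionCell] = []
    if not any_empty:
        D = np.column_stack([masks[c].astype(float) for c in ordered[1:]])
        Xc = np.column_stack([np.ones(len(es)), C, D])
        fit_c = sm.OLS(es, Xc).fit()
        off = 1 + C.shape[1]
        for t, c in enumerate(ordered):
            n, mean, sd = _cell_stats(es, masks[c])
            if t == 0:
                cells.append(InteractionCell(c[0], c[1], n, mean, sd,
                                             np.nan, np.nan, np.nan, True))
            else:
                cells.append(InteractionCell(
                    c[0], c[1], n, mean, sd,
                    float(fit_c.params[off + t - 1]),
                    float(fit_c.bse[off + t - 1]),
                    float(fit_c.pvalues[off + t - 1])))
    else:
        for t, c in enumerate(ordered):
            n, mean, sd = _cell_stats(es, masks[c])
            cells.append(InteractionCell(c[0], c[1], n, mean, sd,
                                         np.nan, np.nan, np.nan, t == 0))
    return InteractionResult(factor_a=name_a, factor_b=name_b, cells=cells,
                             interaction_p=interaction_p)


# --------------------------------------------------------------------------
# family-level scans with FDR
# --------------------------------------------------------------------------

def _aligned_codes(top_snps, panel, slopes, cov, drop_covariate=None,
                   endotoxin_order="log_of_mean"):
    idx, y, C_full = align_cohort(panel, slopes, cov,
                                  endotoxin_order=endotoxin_order)
    from .association import ADJUSTMENT_COVARIATES
    names = list(ADJUSTMENT_COVARIATES)
    if drop_covariate is not None:
        keep = [t for t, nm in enumerate(names) if nm != drop_covariate]
        C = C_full[:, keep]
    else:
        C = C_full
    codes = {}
    for sid in top_snps:
        j = panel.snp_index(sid)
        code, reason = encode_genotype(panel.calls[idx, j], "dominant")
        if reason is not None:
            raise ValueError(f"SNP {sid} not testable: {reason}")
        codes[sid] = code
    return idx, y, C, codes


def pairwise_scan(top_snps: list[str], panel: GenotypePanel,
                  slopes: pd.DataFrame, cov: CovariateTable
                  ) -> list[InteractionResult]:
    """All C(k,2) gene–gene interactions among ``top_snps`` with BH
    q-values over the family of pair P-values."""
    if len(top_snps) < 2:
        raise ValueError("need at least 2 SNPs")
    _, y, C, codes = _aligned_codes(top_snps, panel, slopes, cov)
    results = []
    for i in range(len(top_snps)):
        for j in range(i + 1, len(top_snps)):
            a, b = top_snps[i], top_snps[j]
            results.append(fit_gene_gene(y, codes[a], codes[b], C,
                                         name_a=a, name_b=b))
    q = bh_fdr([r.interaction_p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
    return results


def environment_scan(top_snps: list[str], panel: GenotypePanel,
                     slopes: pd.DataFrame, cov: CovariateTable,
                     env_values: pd.Series, env_name: str,
                     drop_covariate: str | None = None,
                     levels: list | None = None) -> list[InteractionResult]:
    """Gene–environment interactions of each top SNP with one factor;
    BH q-values within this family (k tests)."""
    idx, y, C, codes = _aligned_codes(top_snps, panel, slopes, cov,
                                      drop_covariate=drop_covariate)
    env = env_values.loc[[panel.subjects[t] for t in idx]].to_numpy()
    results = []
    for sid in top_snps:
        results.append(fit_gene_environment(y, codes[sid], env, C,
                                            name_a=sid, name_b=env_name,
                                            levels=levels))
    q = bh_fdr([r.interaction_p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
    return results
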