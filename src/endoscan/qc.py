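"""Genotype quality control: the SNP and sample filter cascade.

SNP-level filters run sequentially — non-autosomal chromosome, call rate,
minor allele frequency, Hardy–Weinberg exact test — and each SNP is
charged to the *first* criterion it fails, reproducing single-pass
bookkeeping.  Sample-level filters then remove subjects by call rate,
cryptic relatedness (mean identity-by-state sharing) and principal-
component outlyingness.

Threshold conventions worth noting: SNP call rate removes at ``<= 0.95``
while subject call rate removes at ``< 0.95`` — the asymmetry is
deliberate and matches how chip-QC reports are usually worded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .io_formats import MISSING, GenotypePanel


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs of the filter cascade (see module docstring for boundary
    conventions)."""

    snp_call_rate_max_removed: float = 0.95  # remove SNP if call rate <= this
    maf_min: float = 0.05                    # remove SNP if MAF < this
    hwe_p_min: float = 1e-3                  # remove SNP if exact P < this
    subject_call_rate_min: float = 0.95      # remove subject if call rate < this
    relatedness_ibs_max: float = 0.9         # remove one of a pair if mean IBS > this
    outlier_sd: float = 6.0                  # remove subject if |PC score z| > this
    n_pcs: int = 10                          # PCs examined by the outlier rule

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_max_removed", "maf_min", "hwe_p_min",
                     "subject_call_rate_min", "relatedness_ibs_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


@dataclass
class QCReport:
    """Ordered per-criterion removal counts plus the surviving sizes."""

    removed: list[tuple[str, int]]
    survivors: tuple[int, int]  # (n_subjects, n_snps)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def total_removed(self) -> int:
        return sum(n for _, n in self.removed)


# --------------------------------------------------------------------------
# Hardy–Weinberg exact test
# --------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy–Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose point probability does not exceed
    that of the observed table.  Returns a P in (0, 1].
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("all genotype counts are zero")
    na = 2 * n_hom_minor + n_het       # copies of one allele
    nb = 2 * n - na                    # copies of the other
    if na > nb:
        na, nb = nb, na
    # possible heterozygote counts share the parity of na
    hets = np.arange(na % 2, na + 1, 2)
    n1 = (na - hets) // 2              # rarer-allele homozygotes
    n2 = (nb - hets) // 2
    logw = (hets * np.log(2.0)
            - gammaln(n1 + 1) - gammaln(hets + 1) - gammaln(n2 + 1))
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    obs = int(n_het)
    p_obs = w[np.searchsorted(hets, obs)]
    p = float(w[w <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_pvalues(panel: GenotypePanel, snp_idx: np.ndarray | None = None) -> np.ndarray:
    """Exact HWE P per SNP, computed on non-missing calls.

    The code-2 homozygote need not be the minor one; the test is
    symmetric in the two alleles so counts are passed as observed.
    """
    counts = panel.genotype_counts()
    idx = np.arange(panel.n_snps) if snp_idx is None else np.asarray(snp_idx)
    out = np.ones(len(idx))
    for k, j in enumerate(idx):
        c0, c1, c2 = (int(v) for v in counts[j])
        if c0 + c1 + c2 == 0:
            out[k] = np.nan
            continue
        out[k] = hwe_exact_test(min(c0, c2), c1, max(c0, c2))
    return out


# --------------------------------------------------------------------------
# SNP filter cascade
# --------------------------------------------------------------------------

def snp_filter(panel: GenotypePanel, thresholds: QCThresholds | None = None
               ) -> tuple[GenotypePanel, QCReport]:
    """Remove SNPs failing, in order: non-autosomal chromosome, call rate,
    MAF, HWE.  Each SNP is charged to the first criterion it fails."""
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    thr = thresholds or QCThresholds()

    remaining = np.ones(panel.n_snps, dtype=bool)
    removed: list[tuple[str, int]] = []
    removed_ids: dict[str, list[str]] = {}
    ids = np.array(panel.snp_ids)

    def _strike(mask: np.ndarray, label: str) -> None:
        mask = mask & remaining
        removed.append((label, int(mask.sum())))
        removed_ids[label] = list(ids[mask])
        remaining[mask] = False

    autosomal = np.array([s.is_autosomal for s in panel.snps])
    _strike(~autosomal, "non_autosomal")

    call_rate = panel.snp_call_rates()
    _strike(call_rate <= thr.snp_call_rate_max_removed, "snp_call_rate")

    maf = panel.minor_allele_freq()
    with np.errstate(invalid="ignore"):
        _strike(np.nan_to_num(maf, nan=0.0) < thr.maf_min, "maf")

    idx = np.flatnonzero(remaining)
    hwe_p = hwe_pvalues(panel, idx)
    fail = np.zeros(panel.n_snps, dtype=bool)
    fail[idx] = np.nan_to_num(hwe_p, nan=1.0) < thr.hwe_p_min
    _strike(fail, "hwe")

    keep = np.flatnonzero(remaining)
    filtered = panel.subset(snp_idx=keep)
    report = QCReport(removed=removed,
                      survivors=(panel.n_subjects, len(keep)),
                      removed_ids=removed_ids)
    return filtered, report


# --------------------------------------------------------------------------
# Sample filter cascade
# --------------------------------------------------------------------------

def pairwise_ibs(calls: np.ndarray) -> np.ndarray:
    """Mean identity-by-state proportion for every subject pair.

    For each pair, averaged over SNPs non-missing in both: 1 for equal
    genotypes, 0.5 for one shared allele, 0 for opposite homozygotes.
    """
    G = np.asarray(calls)
    ind = [(G == k).astype(np.float64) for k in (0, 1, 2)]
    valid = (G != MISSING).astype(np.float64)
    same = sum(a @ a.T for a in ind)
    diff2 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    n_valid = valid @ valid.T
    diff1 = n_valid - same - diff2
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = (same + 0.5 * diff1) / n_valid
    return ibs


def pca_scores(calls: np.ndarray, n_pcs: int = 10) -> np.ndarray:
    """Principal-component scores of the standardized genotype matrix.

    Missing calls are mean-imputed per SNP; zero-variance SNPs drop out.
    """
    G = np.asarray(calls, dtype=np.float64)
    G[G == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(col_mean, inds[1])
    G -= col_mean
    sd = G.std(axis=0)
    keep = sd > 0
    G = G[:, keep] / sd[keep]
    k = min(n_pcs, min(G.shape) - 1)
    if k < 1:
        return np.zeros((G.shape[0], 0))
    U, S, _ = np.linalg.svd(G, full_matrices=False)
    return U[:, :k] * S[:k]


def sample_filter(panel: GenotypePanel, thresholds: QCThresholds | None = None
                  ) -> tuple[GenotypePanel, QCReport]:
    """Remove subjects by, in order: genotyping call rate, cryptic
    relatedness (one member per high-IBS pair: the lower-call-rate one,
    ties broken toward the later subject), and PC outlyingness (> z SDs
    from the mean on any of the top PCs)."""
    thr = thresholds or QCThresholds()
    subjects = np.array(panel.subjects)
    removed: list[tuple[str, int]] = []
    removed_ids: dict[str, list[str]] = {}

    call_rate = panel.subject_call_rates()
    low = call_rate < thr.subject_call_rate_min
    removed.append(("subject_call_rate", int(low.sum())))
    removed_ids["subject_call_rate"] = list(subjects[low])
    keep = np.flatnonzero(~low)

    # relatedness on surviving subjects
    ibs = pairwise_ibs(panel.calls[keep])
    cr = call_rate[keep]
    n = len(keep)
    iu, ju = np.triu_indices(n, k=1)
    flag = ibs[iu, ju] > thr.relatedness_ibs_max
    pairs = sorted(zip(iu[flag], ju[flag]))
    dropped: set[int] = set()
    for i, j in pairs:
        if i in dropped or j in dropped:
            continue
        if cr[i] < cr[j]:
            victim = i
        elif cr[j] < cr[i]:
            victim = j
        else:
            victim = max(i, j)  # tie: later subject order
        dropped.add(victim)
    removed.append(("relatedness", len(dropped)))
    removed_ids["relatedness"] = [panel.subjects[keep[v]] for v in sorted(dropped)]
    keep = np.array([k for t, k in enumerate(keep) if t not in dropped])

    # PCA outliers
    if len(keep) < 3:
        removed.append(("pca_outlier", 0))
        removed_ids["pca_outlier"] = []
    else:
        scores = pca_scores(panel.calls[keep], n_pcs=thr.n_pcs)
        if scores.shape[1] == 0:
            out_mask = np.zeros(len(keep), dtype=bool)
        else:
            mu = scores.mean(axis=0)
            sd = scores.std(axis=0)
            sd[sd == 0] = 1.0
            z = np.abs((scores - mu) / sd)
            out_mask = (z > thr.outlier_sd).any(axis=1)
        removed.append(("pca_outlier", int(out_mask.sum())))
        removed_ids["pca_outlier"] = list(np.array(panel.subjects)[keep[out_mask]])
        keep = keep[~out_mask]

    filtered = panel.subset(subject_idx=keep)
    report = QCReport(removed=removed,
                      survivors=(len(keep), panel.n_snps),
                      removed_ids=removed_ids)
    return filtered, report


def run_qc(panel: GenotypePanel, thresholds: QCThresholds | None = None
           ) -> tuple[GenotypePanel, QCReport, QCReport]:
    """SNP filters then sample filters, single pass (SNP statistics are
    not recomputed on the post-sample-QC subjects)."""
    p1, snp_report = snp_filter(panel, thresholds)
    p2, sample_report = sample_filter(p1, thresholds)
    return p2, snp_report, sample_report
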