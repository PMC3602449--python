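"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators live here:

* :func:`simulate_cohort` draws a full study — Hardy–Weinberg genotypes,
  a two-component age mixture (young new hires around 18.4 y, older
  transfers around 33.1 y), work-area endotoxin levels, per-subject true
  FEV1 slopes built from dominant SNP effects, covariate effects and
  chosen interactions, and longitudinal FEV1 visits at months 0/3/12/18
  with staged dropout.  A :class:`TruthTable` rides along so parameter-
  recovery tests can compare estimates against what was planted.

* :func:`make_qc_fixture` engineers a panel in which exactly the
  requested numbers of SNPs and subjects violate each QC criterion when
  the filters run in their canonical order, and everything else passes
  with margin.  Genotype counts of passing SNPs are placed at the
  Hardy–Weinberg conditional mode, so no SNP fails a filter by sampling
  accident.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (MISSING, CovariateTable, GenotypePanel,
                         LongitudinalPhenotype, SnpRecord)

# interaction specs: ("gg", snp_i, snp_j, effect) for gene-gene products of
# dominant codes; ("ge", snp_i, covariate_name, effect) for gene-environment
# products of a dominant code with a centered covariate.
InteractionSpec = tuple


@dataclass
class SimulationConfig:
    """Generative settings of a simulated cohort.

    Slopes are in ml/month.  Covariate and interaction effects multiply
    *centered* covariates, so ``slope_intercept`` is the population mean
    slope.  ``dropout_probs[j]`` is the probability of attending visit j
    given attendance at visit j-1; the defaults reproduce a follow-up
    pattern in which roughly 21% of subjects stop after month 3, 14%
    after month 12 and 65% complete month 18.
    """

    n_subjects: int = 301
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    visit_months: tuple[float, ...] = (0.0, 3.0, 12.0, 18.0)
    dropout_probs: tuple[float, ...] = (1.0, 1.0, 0.794, 0.824)
    slope_intercept: float = -6.79
    covariate_effects: dict = field(default_factory=lambda: {
        "age": -0.40, "height": 0.0, "fev1_baseline": -0.003,
        "log_endotoxin": -3.0,
    })
    snp_effects: list = field(default_factory=list)          # (snp index, ml/month)
    interaction_effects: list = field(default_factory=list)  # InteractionSpec
    within_subject_sd: float = 100.0      # ml, FEV1 measurement noise
    between_subject_slope_sd: float = 10.0  # ml/month, unexplained slope spread
    baseline_mean_sd: tuple[float, float] = (2630.0, 350.0)  # ml
    endotoxin_area_levels: tuple[float, ...] = (60.0, 120.0, 163.0, 240.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.within_subject_sd < 0 or self.between_subject_slope_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        months = tuple(self.visit_months)
        if months[0] != 0 or any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit_months must be strictly increasing from 0")
        if len(self.dropout_probs) != len(months):
            raise ValueError("dropout_probs must match visit_months length")
        for idx, _ in self.snp_effects:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"snp_effects index {idx} out of range")
        for spec in self.interaction_effects:
            kind = spec[0]
            if kind == "gg":
                _, i, j, _e = spec
                if not (0 <= i < self.n_snps and 0 <= j < self.n_snps):
                    raise ValueError(f"interaction SNP index out of range: {spec}")
            elif kind == "ge":
                _, i, name, _e = spec
                if not (0 <= i < self.n_snps):
                    raise ValueError(f"interaction SNP index out of range: {spec}")
                if name not in ("age", "height", "fev1_baseline", "log_endotoxin"):
                    raise ValueError(f"unknown covariate in interaction: {name}")
            else:
                raise ValueError(f"unknown interaction kind {kind!r}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("maf_range", "visit_months", "dropout_probs",
                    "baseline_mean_sd", "endotoxin_area_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        raw["snp_effects"] = [tuple(t) for t in raw.get("snp_effects", [])]
        raw["interaction_effects"] = [tuple(t) for t in raw.get("interaction_effects", [])]
        return cls(**raw)


@dataclass
class TruthTable:
    """Ground truth aligned by id with the emitted panel and tables."""

    subjects: pd.DataFrame  # subject, true_slope, baseline, area, covariates
    snps: pd.DataFrame      # snp_id, maf, dominant_effect


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def _snp_records(n_snps: int, rng: np.random.Generator,
                 chromosomes: Sequence[str] | None = None) -> list[SnpRecord]:
    recs = []
    for j in range(n_snps):
        a, b = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        chrom = chromosomes[j] if chromosomes is not None else str(j % 22 + 1)
        recs.append(SnpRecord(f"snp{j:05d}", chrom, 1000 * (j + 1), a, b))
    return recs


def simulate_genotypes(n_subjects: int, mafs: Sequence[float],
                       seed: int | np.random.Generator = 0) -> GenotypePanel:
    """Independent Hardy–Weinberg SNPs; ``allele_b`` carries frequency
    ``maf`` so calls count minor-allele copies."""
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1 or len(mafs) == 0:
        raise ValueError("mafs must be a non-empty 1-D sequence")
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("each maf must lie in (0, 0.5]")
    rng = _as_rng(seed)
    calls = rng.binomial(2, mafs, size=(n_subjects, len(mafs))).astype(np.int8)
    snps = _snp_records(len(mafs), rng)
    subjects = [f"S{i:04d}" for i in range(n_subjects)]
    return GenotypePanel(snps=snps, subjects=subjects, calls=calls)


def duplicate_snp(panel: GenotypePanel, snp_idx: int, flip_prob: float,
                  seed: int | np.random.Generator = 0,
                  new_id: str | None = None) -> GenotypePanel:
    """Append a copy of one SNP's calls with independent per-call flips.

    Supports tests of min-P behaviour under linkage disequilibrium:
    ``flip_prob=0`` yields a perfectly correlated duplicate.
    """
    rng = _as_rng(seed)
    src = panel.snps[snp_idx]
    col = panel.calls[:, snp_idx].copy()
    flip = rng.random(len(col)) < flip_prob
    col[flip & (col != MISSING)] = (col[flip & (col != MISSING)] + 1) % 3
    rec = SnpRecord(new_id or f"{src.snp_id}_dup", src.chromosome,
                    src.position + 1, src.allele_a, src.allele_b)
    return GenotypePanel(snps=panel.snps + [rec],
                         subjects=panel.subjects,
                         calls=np.column_stack([panel.calls, col]))


def _draw_covariates(n: int, cfg: SimulationConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    young = rng.random(n) < 0.542
    age = np.where(young,
                   rng.normal(18.4, 1.5, n),
                   rng.normal(33.1, 5.0, n))
    age = np.clip(age, 16.0, 46.7)
    height = rng.normal(160.0, 5.5, n)
    baseline = np.maximum(rng.normal(*cfg.baseline_mean_sd, n), 800.0)
    area = rng.choice(cfg.endotoxin_area_levels, size=n)
    return pd.DataFrame({
        "subject": [f"S{i:04d}" for i in range(n)],
        "height": height, "age": age, "fev1_baseline": baseline, "area": area,
    })


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[GenotypePanel, LongitudinalPhenotype,
                               CovariateTable, TruthTable]:
    """Draw a full cohort; see the module docstring for the model."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps)
    panel = simulate_genotypes(cfg.n_subjects, mafs, rng)

    covs = _draw_covariates(cfg.n_subjects, cfg, rng)
    months = np.asarray(cfg.visit_months)

    # per-visit endotoxin around the subject's work-area level
    endo_rows = []
    for i in range(cfg.n_subjects):
        lv = covs["area"].iloc[i]
        for m in months:
            endo_rows.append((covs["subject"].iloc[i], float(m),
                              lv * math.exp(rng.normal(0.0, 0.25))))
    endotoxin = pd.DataFrame(endo_rows, columns=["subject", "month", "endotoxin"])

    cov_table = CovariateTable(
        subjects=covs[["subject", "height", "age", "fev1_baseline"]].copy(),
        endotoxin=endotoxin,
    )

    # true slope: intercept + covariate terms (centered) + dominant SNP
    # effects + interactions + between-subject noise
    design = cov_table.design_frame().loc[covs["subject"]]
    centered = design - design.mean(axis=0)
    slope = np.full(cfg.n_subjects, cfg.slope_intercept, dtype=float)
    for name, eff in cfg.covariate_effects.items():
        slope += eff * centered[name].to_numpy()
    dom = (panel.calls >= 1).astype(float)
    for idx, eff in cfg.snp_effects:
        slope += eff * dom[:, idx]
    for spec in cfg.interaction_effects:
        if spec[0] == "gg":
            _, i, j, eff = spec
            slope += eff * dom[:, i] * dom[:, j]
        else:
            _, i, name, eff = spec
            slope += eff * dom[:, i] * centered[name].to_numpy()
    slope += rng.normal(0.0, cfg.between_subject_slope_sd, cfg.n_subjects)

    baseline = np.maximum(rng.normal(*cfg.baseline_mean_sd, cfg.n_subjects), 800.0)

    # staged dropout: attend visit j only if visit j-1 was attended
    pheno_rows = []
    for i in range(cfg.n_subjects):
        attending = True
        for j, m in enumerate(months):
            if j > 0:
                attending = attending and (rng.random() < cfg.dropout_probs[j])
            if not attending:
                break
            fev = baseline[i] + slope[i] * m
            if cfg.within_subject_sd > 0:
                fev += rng.normal(0.0, cfg.within_subject_sd)
            pheno_rows.append((covs["subject"].iloc[i], float(m), max(fev, 200.0)))
    pheno = LongitudinalPhenotype(
        pd.DataFrame(pheno_rows, columns=["subject", "month", "fev1"]))

    snp_eff = dict(cfg.snp_effects)
    truth = TruthTable(
        subjects=pd.DataFrame({
            "subject": covs["subject"],
            "true_slope": slope,
            "baseline": baseline,
            "height": covs["height"], "age": covs["age"],
            "fev1_baseline": covs["fev1_baseline"], "area": covs["area"],
        }),
        snps=pd.DataFrame({
            "snp_id": panel.snp_ids,
            "maf": mafs,
            "dominant_effect": [snp_eff.get(j, 0.0) for j in range(cfg.n_snps)],
        }),
    )
    return panel, pheno, cov_table, truth


# --------------------------------------------------------------------------
# Engineered QC fixture
# --------------------------------------------------------------------------

def _mode_counts(n: int, p: float) -> tuple[int, int, int]:
    """Genotype counts at (rounded) Hardy–Weinberg expectation."""
    n_hom_minor = round(p * p * n)
    n_het = round(2 * p * (1 - p) * n)
    return n_hom_minor, n_het, n - n_hom_minor - n_het


def _column_multiset(n: int, counts: tuple[int, int, int], n_missing: int = 0
                     ) -> np.ndarray:
    c2, c1, c0 = counts  # hom minor (code 2), het, hom major (code 0)
    body = np.concatenate([
        np.full(n_missing, MISSING), np.full(c2, 2),
        np.full(c1, 1), np.full(c0, 0)])
    if len(body) != n:
        raise ValueError("multiset does not sum to n")
    return body.astype(np.int8)


def make_qc_fixture(n_subjects: int, n_snps: int, n_nonautosomal: int = 0,
                    n_low_callrate: int = 0, n_low_maf: int = 0,
                    n_hwe_fail: int = 0, n_subject_low_callrate: int = 0,
                    n_related: int = 0, n_outliers: int = 0,
                    seed: int = 0) -> GenotypePanel:
    """Panel in which exactly the requested counts violate each QC
    criterion under the canonical filter order, and nothing else does.

    SNP categories are disjoint; a SNP charged to an early criterion may
    or may not satisfy later ones (attribution is first-failure).
    Related subjects are near-duplicates appended after their source
    subjects; outliers are drawn from allele frequencies shifted by
    +0.4, which puts them far out on the leading principal component.
    """
    from .qc import hwe_exact_test  # deferred: avoid import cycle

    n_snp_bad = n_nonautosomal + n_low_callrate + n_low_maf + n_hwe_fail
    n_sub_bad = n_subject_low_callrate + n_related + n_outliers
    if n_snp_bad > n_snps:
        raise ValueError("SNP violation counts exceed n_snps")
    if n_sub_bad >= n_subjects:
        raise ValueError("subject violation counts exceed n_subjects")
    n_clean_sub = n_subjects - n_sub_bad
    if n_related > n_clean_sub:
        raise ValueError("need one clean source subject per related duplicate")
    n_regular = n_clean_sub + n_subject_low_callrate
    if n_hwe_fail and hwe_exact_test(0, n_regular, 0) >= 1e-3:
        raise ValueError(
            f"too few subjects ({n_regular}) to engineer a definitive "
            "Hardy-Weinberg failure")

    rng = np.random.default_rng(seed)
    n_pass = n_snps - n_snp_bad
    pass_mafs = (0.20, 0.30, 0.40, 0.45)

    # --- per-SNP genotype multisets over the regular subjects ---
    cols = np.empty((n_regular, n_snps), dtype=np.int8)
    chroms: list[str] = []
    ids: list[str] = []
    j = 0
    base_freq = np.empty(n_snps)  # allele-b frequency, for outlier draws

    def _add(label: str, chrom: str, counts: tuple[int, int, int],
             n_missing: int = 0) -> None:
        nonlocal j
        cols[:, j] = _column_multiset(n_regular, counts, n_missing)
        chroms.append(chrom)
        ids.append(f"{label}{j:05d}")
        nn = n_regular - n_missing
        base_freq[j] = (counts[0] * 2 + counts[1]) / (2.0 * nn) if nn else 0.5
        j += 1

    for k in range(n_nonautosomal):
        _add("nonauto", "X", _mode_counts(n_regular, pass_mafs[k % 4]))
    n_miss = max(1, math.ceil(0.08 * n_regular))
    for k in range(n_low_callrate):
        _add("lowcr", str(k % 22 + 1),
             _mode_counts(n_regular - n_miss, pass_mafs[k % 4]), n_miss)
    for k in range(n_low_maf):
        _add("lowmaf", str(k % 22 + 1), _mode_counts(n_regular, 0.02))
    for k in range(n_hwe_fail):
        _add("hwefail", str(k % 22 + 1), (0, n_regular, 0))
    for k in range(n_pass):
        _add("ok", str(k % 22 + 1), _mode_counts(n_regular, pass_mafs[k % 4]))

    # shuffle genotypes within each column (keeps counts exact, breaks
    # any subject-level structure) and shuffle SNP order
    cols = rng.permuted(cols, axis=0)
    order = rng.permutation(n_snps)
    cols = cols[:, order]
    chroms = [chroms[t] for t in order]
    ids = [ids[t] for t in order]
    base_freq = base_freq[order]

    # --- subject blocks ---
    clean = cols[:n_clean_sub]
    lowcr_sub = cols[n_clean_sub:]
    if n_subject_low_callrate:
        lowcr_sub = lowcr_sub.copy()
        mask = rng.random(lowcr_sub.shape) < 0.08
        lowcr_sub[mask] = MISSING

    dup_rows = []
    for k in range(n_related):
        row = clean[k].copy()
        flip = (rng.random(n_snps) < 0.02) & (row != MISSING)
        row[flip] = (row[flip] + 1) % 3
        dup_rows.append(row)

    out_rows = []
    if n_outliers:
        q = np.clip(base_freq + 0.4, 0.02, 0.95)
        for _ in range(n_outliers):
            out_rows.append(rng.binomial(2, q).astype(np.int8))

    blocks = [clean]
    if n_subject_low_callrate:
        blocks.append(lowcr_sub)
    if dup_rows:
        blocks.append(np.vstack(dup_rows))
    if out_rows:
        blocks.append(np.vstack(out_rows))
    calls = np.vstack(blocks)

    subjects = ([f"S{i:04d}" for i in range(n_clean_sub)]
                + [f"LCR{i:04d}" for i in range(n_subject_low_callrate)]
                + [f"DUP{i:04d}" for i in range(n_related)]
                + [f"OUT{i:04d}" for i in range(n_outliers)])

    snps = []
    for t in range(n_snps):
        a, b = _ALLELE_PAIRS[t % len(_ALLELE_PAIRS)]
        snps.append(SnpRecord(ids[t], chroms[t], 1000 * (t + 1), a, b))
    return GenotypePanel(snps=snps, subjects=subjects, calls=calls)
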