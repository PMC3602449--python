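"""Domain containers and text-format I/O for the pipeline.

Genotypes live in a :class:`GenotypePanel`: an ordered SNP list plus a
subjects × SNPs call matrix coded ``0`` (homozygous for ``allele_a``),
``1`` (heterozygous), ``2`` (homozygous for ``allele_b``) and ``-1``
(missing).  ``allele_a`` is always the lexicographically smaller of a
SNP's two alleles; the *minor* allele is a frequency statement, computed
on demand, never stored.

Longitudinal FEV1 measurements, covariates and result tables are plain
pandas DataFrames with documented columns; thin wrappers add the
invariant checks the rest of the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
VALID_ALLELES = frozenset("ACGT")
AUTOSOMES = frozenset(str(c) for c in range(1, 23))
VALID_CHROMOSOMES = AUTOSOMES | {"X", "Y", "XY", "MT"}


class FormatError(ValueError):
    """A text input violates the PED/MAP or table contract."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: identity, map position and its two alleles."""

    snp_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise FormatError("empty snp_id")
        if str(self.chromosome) not in VALID_CHROMOSOMES:
            raise FormatError(f"bad chromosome {self.chromosome!r} for {self.snp_id}")
        if self.position < 1:
            raise FormatError(f"position must be 1-based positive for {self.snp_id}")
        for al in (self.allele_a, self.allele_b):
            if al not in VALID_ALLELES:
                raise FormatError(f"bad allele {al!r} for {self.snp_id}")
        if self.allele_a == self.allele_b:
            raise FormatError(f"alleles must differ for {self.snp_id}")

    @property
    def is_autosomal(self) -> bool:
        return str(self.chromosome) in AUTOSOMES


@dataclass
class GenotypePanel:
    """Subjects × SNPs genotype calls plus per-SNP metadata."""

    snps: list[SnpRecord]
    subjects: list[str]
    calls: np.ndarray  # int8, shape (n_subjects, n_snps), values {0,1,2,-1}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.subjects), len(self.snps)):
            raise FormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        if len({s.snp_id for s in self.snps}) != len(self.snps):
            raise FormatError("duplicate snp_id in panel")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("call matrix contains codes outside {0,1,2,-1}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    # ---- per-SNP summaries (computed on non-missing calls) ----

    def snp_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def subject_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """(n_snps, 3) counts of codes 0/1/2 among non-missing calls."""
        out = np.empty((self.n_snps, 3), dtype=np.int64)
        for k in range(3):
            out[:, k] = (self.calls == k).sum(axis=0)
        return out

    def allele_b_freq(self) -> np.ndarray:
        counts = self.genotype_counts()
        n = counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return (counts[:, 1] + 2 * counts[:, 2]) / (2.0 * n)

    def minor_allele_freq(self) -> np.ndarray:
        f = self.allele_b_freq()
        return np.minimum(f, 1.0 - f)

    def subset(self, subject_idx: Sequence[int] | np.ndarray | None = None,
               snp_idx: Sequence[int] | np.ndarray | None = None) -> "GenotypePanel":
        si = np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        sj = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypePanel(
            snps=[self.snps[j] for j in sj],
            subjects=[self.subjects[i] for i in si],
            calls=self.calls[np.ix_(si, sj)].copy(),
        )


@dataclass
class LongitudinalPhenotype:
    """Long-format FEV1 records: one row per (subject, month) visit."""

    records: pd.DataFrame  # columns: subject, month, fev1 (ml)

    def __post_init__(self) -> None:
        required = {"subject", "month", "fev1"}
        if not required.issubset(self.records.columns):
            raise FormatError(f"phenotype table needs columns {sorted(required)}")
        if (self.records["month"] < 0).any():
            raise FormatError("negative month in phenotype table")
        if (self.records["fev1"] <= 0).any():
            raise FormatError("non-positive FEV1 in phenotype table")

    def subjects(self) -> list[str]:
        return list(self.records["subject"].unique())


@dataclass
class CovariateTable:
    """Per-subject covariates plus per-visit endotoxin exposures.

    ``subjects`` has one row per subject (columns: subject, height [cm],
    age [years], fev1_baseline [ml]); ``endotoxin`` is long-format
    (subject, month, endotoxin [EU/m3]).
    """

    subjects: pd.DataFrame
    endotoxin: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"subject", "height", "age", "fev1_baseline"}
        if not need.issubset(self.subjects.columns):
            raise FormatError(f"covariate table needs columns {sorted(need)}")
        need_e = {"subject", "month", "endotoxin"}
        if not need_e.issubset(self.endotoxin.columns):
            raise FormatError(f"endotoxin table needs columns {sorted(need_e)}")
        for col in ("height", "age", "fev1_baseline"):
            if (self.subjects[col] <= 0).any():
                raise FormatError(f"non-positive {col} in covariate table")
        if (self.endotoxin["endotoxin"] <= 0).any():
            raise FormatError("non-positive endotoxin exposure")

    def mean_log_endotoxin(self, order: str = "log_of_mean") -> pd.Series:
        """Per-subject endotoxin summary used as the exposure covariate.

        ``order='log_of_mean'`` takes the natural log of each subject's
        across-visit mean exposure; ``'mean_of_log'`` averages the
        per-visit logs.  Both are exposed because "average level of
        log-transformed exposure" admits either reading.
        """
        g = self.endotoxin.groupby("subject")["endotoxin"]
        if order == "log_of_mean":
            out = np.log(g.mean())
        elif order == "mean_of_log":
            out = np.log(self.endotoxin.set_index("subject")["endotoxin"]).groupby(level=0).mean()
        else:
            raise ValueError(f"unknown endotoxin summary order {order!r}")
        out.name = "log_endotoxin"
        return out

    def design_frame(self, endotoxin_order: str = "log_of_mean") -> pd.DataFrame:
        """Wide per-subject frame with the four adjustment covariates."""
        df = self.subjects.set_index("subject")[["height", "age", "fev1_baseline"]].copy()
        df["log_endotoxin"] = self.mean_log_endotoxin(order=endotoxin_order)
        return df


# --------------------------------------------------------------------------
# PLINK PED/MAP text dialect
# --------------------------------------------------------------------------

def read_genotype_panel(ped_path: str | Path, map_path: str | Path) -> GenotypePanel:
    """Read a PED/MAP pair into a :class:`GenotypePanel`.

    Of the six leading PED columns only the individual id is kept; "0 0"
    allele pairs become missing calls.  ``allele_a`` is the smaller
    observed allele character, ``allele_b`` the other.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 MAP columns")
            chrom, snp_id, _cm, pos = parts[:4]
            map_rows.append((snp_id, chrom, int(pos)))
    n_snps = len(map_rows)

    subjects: list[str] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"({n_snps} SNPs), got {len(parts)}"
                )
            subjects.append(parts[1])
            row = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)]
            allele_pairs.append(row)

    calls = np.full((len(subjects), n_snps), MISSING, dtype=np.int8)
    snps: list[SnpRecord] = []
    for j, (snp_id, chrom, pos) in enumerate(map_rows):
        observed: set[str] = set()
        for i in range(len(subjects)):
            a1, a2 = allele_pairs[i][j]
            for al in (a1, a2):
                if al != "0":
                    observed.add(al)
        if len(observed) > 2:
            raise FormatError(f"SNP {snp_id}: more than 2 alleles {sorted(observed)}")
        if not observed <= VALID_ALLELES:
            raise FormatError(f"SNP {snp_id}: invalid alleles {sorted(observed - VALID_ALLELES)}")
        ordered = sorted(observed)
        if len(ordered) == 0:
            # fully missing column; pick placeholder alleles
            ordered = ["A", "C"]
        elif len(ordered) == 1:
            # monomorphic: second allele is the next character, just to
            # satisfy the record contract; it never appears in calls
            other = sorted(VALID_ALLELES - set(ordered))[0]
            ordered = sorted([ordered[0], other])
        allele_a, allele_b = ordered[0], ordered[1]
        snps.append(SnpRecord(snp_id, chrom, pos, allele_a, allele_b))
        for i in range(len(subjects)):
            a1, a2 = allele_pairs[i][j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == allele_b) + (a2 == allele_b)
    return GenotypePanel(snps=snps, subjects=subjects, calls=calls)


def write_genotype_panel(panel: GenotypePanel, ped_path: str | Path,
                         map_path: str | Path) -> None:
    """Write a panel as a PED/MAP pair (missing calls as "0 0")."""
    with open(map_path, "w") as fh:
        for s in panel.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    code_to_pair = {}
    with open(ped_path, "w") as fh:
        for i, subj in enumerate(panel.subjects):
            fields = [subj, subj, "0", "0", "2", "-9"]  # all-female cohort
            for j, s in enumerate(panel.snps):
                c = panel.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [s.allele_a, s.allele_a]
                elif c == 1:
                    fields += [s.allele_a, s.allele_b]
                else:
                    fields += [s.allele_b, s.allele_b]
            fh.write(" ".join(fields) + "\n")
    del code_to_pair


# --------------------------------------------------------------------------
# TSV result/table plumbing
# --------------------------------------------------------------------------

def write_results_table(rows: Iterable, path: str | Path,
                        columns: Sequence[str] | None = None) -> None:
    """Write result records as a TSV with header and stable column order.

    ``rows`` may be dataclass instances, dicts or a DataFrame.  Floats
    are rendered with 9 significant digits so a read-back reproduces
    them to well below 1e-9 relative error.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        recs = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                recs.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                recs.append(dict(r))
        df = pd.DataFrame(recs, columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_phenotype(path: str | Path) -> LongitudinalPhenotype:
    return LongitudinalPhenotype(pd.read_csv(path, sep="\t"))


def write_phenotype(pheno: LongitudinalPhenotype, path: str | Path) -> None:
    pheno.records.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_covariates(subjects_path: str | Path, endotoxin_path: str | Path) -> CovariateTable:
    return CovariateTable(
        subjects=pd.read_csv(subjects_path, sep="\t"),
        endotoxin=pd.read_csv(endotoxin_path, sep="\t"),
    )


def write_covariates(cov: CovariateTable, subjects_path: str | Path,
                     endotoxin_path: str | Path) -> None:
    cov.subjects.to_csv(subjects_path, sep="\t", index=False, float_format="%.9g")
    cov.endotoxin.to_csv(endotoxin_path, sep="\t", index=False, float_format="%.9g")
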