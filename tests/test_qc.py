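from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from endoscan.io_formats import GenotypePanel, SnpRecord
from endoscan.qc import (QCThresholds, hwe_exact_test, pairwise_ibs,
                         sample_filter, snp_filter)
from endoscan.synthetic import make_qc_fixture, simulate_genotypes

from conftest import child_seed


def hwe_enumeration_oracle(n_hom_minor, n_het, n_hom_major):
    """Exact-rational enumeration over all heterozygote counts."""
    n = n_hom_minor + n_het + n_hom_major
    na = 2 * n_hom_minor + n_het
    nb = 2 * n - na
    if na > nb:
        na, nb = nb, na
    weights = {}
    for h in range(na % 2, na + 1, 2):
        n1, n2 = (na - h) // 2, (nb - h) // 2
        weights[h] = Fraction(2**h, factorial(n1) * factorial(h) * factorial(n2))
    w_obs = weights[n_het]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(tail, total))


class TestHweExactTest:
    def test_mode_table_gives_one(self):
        assert hwe_exact_test(25, 50, 25) == 1.0

    @pytest.mark.parametrize("counts", [(3, 1, 3), (0, 10, 0), (2, 5, 13),
                                        (0, 1, 19), (5, 0, 5)])
    def test_matches_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12)

    def test_all_small_tables(self):
        # exhaustive agreement for every genotype table with total <= 25
        # (the larger sweep to 50 lives in the acceptance suite)
        for n in range(1, 26):
            for n1 in range(n + 1):
                for nh in range(n - n1 + 1):
                    c = (n1, nh, n - n1 - nh)
                    assert hwe_exact_test(*c) == pytest.approx(
                        hwe_enumeration_oracle(*c), abs=1e-10), c

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


def _random_messy_panel(seed, n_subjects=80, n_snps=120):
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(0.01, 0.5, n_snps)
    panel = simulate_genotypes(n_subjects, mafs, seed=seed)
    miss = rng.random(panel.calls.shape) < rng.uniform(0, 0.1, n_snps)
    calls = panel.calls.copy()
    calls[miss] = -1
    snps = [SnpRecord(s.snp_id, "X" if j % 17 == 0 else s.chromosome,
                      s.position, s.allele_a, s.allele_b)
            for j, s in enumerate(panel.snps)]
    return GenotypePanel(snps=snps, subjects=panel.subjects, calls=calls)


class TestSnpFilter:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_against_per_snp_recheck_oracle(self, seed):
        panel = _random_messy_panel(child_seed(7, seed))
        rng = np.random.default_rng(seed)
        thr = QCThresholds(
            snp_call_rate_max_removed=float(rng.uniform(0.9, 0.99)),
            maf_min=float(rng.uniform(0.01, 0.1)),
            hwe_p_min=float(rng.uniform(1e-4, 0.05)))
        filtered, rep = snp_filter(panel, thr)
        survivors = set(filtered.snp_ids)
        # independent per-SNP re-evaluation
        expect = set()
        for j, s in enumerate(panel.snps):
            col = panel.calls[:, j]
            obs = col[col != -1]
            if s.chromosome not in {str(c) for c in range(1, 23)}:
                continue
            if len(obs) / len(col) <= thr.snp_call_rate_max_removed:
                continue
            f = (2 * (obs == 2).sum() + (obs == 1).sum()) / (2 * len(obs))
            if min(f, 1 - f) < thr.maf_min:
                continue
            if hwe_enumeration_oracle(int((obs == 2).sum()), int((obs == 1).sum()),
                                      int((obs == 0).sum())) < thr.hwe_p_min:
                continue
            expect.add(s.snp_id)
        assert survivors == expect
        assert panel.n_snps - rep.total_removed() == rep.survivors[1]

    def test_near_zero_thresholds_remove_only_nonautosomal(self):
        panel = _random_messy_panel(11)
        thr = QCThresholds(snp_call_rate_max_removed=1e-9, maf_min=1e-12,
                           hwe_p_min=1e-300)
        _, rep = snp_filter(panel, thr)
        removed = dict(rep.removed)
        assert removed["snp_call_rate"] == 0
        assert removed["maf"] == 0
        assert removed["hwe"] == 0
        assert removed["non_autosomal"] > 0

    def test_order_permutation_keeps_survivor_set(self):
        # disjoint engineered categories: attribution depends on order,
        # the survivor set does not
        panel = make_qc_fixture(n_subjects=120, n_snps=300, n_nonautosomal=10,
                                n_low_callrate=10, n_low_maf=40, n_hwe_fail=5,
                                seed=3)
        filtered, _ = snp_filter(panel)
        thr = QCThresholds()
        fail_any = set()
        for j, s in enumerate(panel.snps):
            col = panel.calls[:, j]
            obs = col[col != -1]
            f = (2 * (obs == 2).sum() + (obs == 1).sum()) / (2 * len(obs))
            checks = [
                s.chromosome not in {str(c) for c in range(1, 23)},
                len(obs) / len(col) <= thr.snp_call_rate_max_removed,
                min(f, 1 - f) < thr.maf_min,
                hwe_exact_test(int(min((obs == 0).sum(), (obs == 2).sum())),
                               int((obs == 1).sum()),
                               int(max((obs == 0).sum(), (obs == 2).sum())))
                < thr.hwe_p_min,
            ]
            if any(checks):
                fail_any.add(s.snp_id)
        assert set(filtered.snp_ids) == set(panel.snp_ids) - fail_any


class TestSampleFilter:
    def test_clean_panel_removes_nobody(self):
        panel = simulate_genotypes(60, np.full(300, 0.3), seed=8)
        _, rep = sample_filter(panel)
        assert rep.survivors[0] == 60
        assert all(n == 0 for _, n in rep.removed)

    def test_planted_duplicates_vs_ibs_oracle(self):
        rng = np.random.default_rng(9)
        panel = simulate_genotypes(50, rng.uniform(0.2, 0.5, 400), seed=9)
        calls = np.vstack([panel.calls, panel.calls[3], panel.calls[17]])
        subjects = panel.subjects + ["dup3", "dup17"]
        dup_panel = GenotypePanel(snps=panel.snps, subjects=subjects, calls=calls)
        # brute-force pairwise IBS oracle
        n = len(subjects)
        ibs = pairwise_ibs(calls)
        for i in range(0, n, 7):
            for j in range(i + 1, n, 5):
                shared = [1 - abs(int(a) - int(b)) / 2
                          for a, b in zip(calls[i], calls[j])
                          if a != -1 and b != -1]
                assert ibs[i, j] == pytest.approx(np.mean(shared), abs=1e-12)
        filtered, rep = sample_filter(dup_panel)
        removed = dict(rep.removed)
        assert removed["relatedness"] == 2
        # exactly the later member of each duplicate pair is dropped
        assert set(rep.removed_ids["relatedness"]) == {"dup3", "dup17"}
        assert filtered.n_subjects == 50

    def test_report_reconciles(self):
        panel = make_qc_fixture(n_subjects=120, n_snps=500,
                                n_subject_low_callrate=2, n_related=3,
                                n_outliers=2, seed=13)
        filtered, rep = sample_filter(panel)
        assert dict(rep.removed) == {"subject_call_rate": 2,
                                     "relatedness": 3, "pca_outlier": 2}
        assert panel.n_subjects - rep.total_removed() == rep.survivors[0]
        assert filtered.n_subjects == rep.survivors[0]
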