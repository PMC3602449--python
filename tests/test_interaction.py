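import numpy as np
import pytest
from scipy import stats

from endoscan.interaction import (environment_scan, fit_gene_environment,
                                  fit_gene_gene, pairwise_scan)
from endoscan.grs import age_bands
from endoscan.slopes import estimate_all_slopes
from endoscan.synthetic import SimulationConfig, simulate_cohort

from conftest import child_seed


def toy_design(seed=0, n=200):
    rng = np.random.default_rng(seed)
    A = rng.integers(0, 2, n).astype(float)
    B = rng.integers(0, 2, n).astype(float)
    cov = rng.normal(size=(n, 2))
    return rng, A, B, cov


class TestFitGeneGene:
    def test_no_product_zero_noise_gives_zero_coefficient(self):
        _, A, B, cov = toy_design(1)
        es = 3.0 - 5.0 * A + 2.0 * B + cov @ [1.0, -1.0]
        res = fit_gene_gene(es, A, B, cov)
        assert res.product_beta == pytest.approx(0.0, abs=1e-9)

    def test_planted_synergy_recovered_exactly(self):
        _, A, B, cov = toy_design(2)
        es = 3.0 - 5.0 * A + 2.0 * B - 20.0 * A * B + cov @ [1.0, -1.0]
        res = fit_gene_gene(es, A, B, cov)
        assert res.product_beta == pytest.approx(-20.0, abs=1e-8)
        cell11 = next(c for c in res.cells if (c.level_a, c.level_b) == (1, 1))
        assert cell11.beta == pytest.approx(-5.0 + 2.0 - 20.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_product_model_matches_normal_equations(self, seed):
        rng, A, B, cov = toy_design(seed, n=40)
        es = rng.normal(size=40)
        res = fit_gene_gene(es, A, B, cov)
        X = np.column_stack([np.ones(40), cov, A, B, A * B])
        beta = np.linalg.pinv(X.T @ X) @ X.T @ es
        assert res.product_beta == pytest.approx(beta[-1], abs=1e-10)

    def test_joint_cells_are_reparameterization(self):
        rng, A, B, cov = toy_design(5)
        es = rng.normal(size=200) - 4 * A * B
        res = fit_gene_gene(es, A, B, cov)
        by_lv = {(c.level_a, c.level_b): c for c in res.cells}
        # cell contrasts are linear combinations of the product-model
        # coefficients: (1,1) = A + B + AB
        X = np.column_stack([np.ones(200), cov, A, B, A * B])
        b = np.linalg.pinv(X.T @ X) @ X.T @ es
        assert by_lv[(0, 1)].beta == pytest.approx(b[-2], abs=1e-8)
        assert by_lv[(1, 0)].beta == pytest.approx(b[-3], abs=1e-8)
        assert by_lv[(1, 1)].beta == pytest.approx(b[-3] + b[-2] + b[-1],
                                                   abs=1e-8)

    def test_empty_cell_flags_cells_keeps_counts(self):
        _, A, B, cov = toy_design(6)
        B2 = B.copy()
        B2[A == 1] = 0.0  # no (1,1) cell
        es = np.random.default_rng(1).normal(size=200)
        res = fit_gene_gene(es, A, B2, cov)
        by_lv = {(c.level_a, c.level_b): c for c in res.cells}
        assert by_lv[(1, 1)].n == 0
        assert np.isnan(by_lv[(1, 0)].beta)


class TestFitGeneEnvironment:
    def test_constant_genotype_effect_zero_f(self):
        rng = np.random.default_rng(7)
        n = 300
        A = rng.integers(0, 2, n).astype(float)
        env = rng.choice(["<18", "18-25", ">=25"], n)
        cov = rng.normal(size=(n, 2))
        env_eff = np.select([env == "<18", env == "18-25"], [0.0, -4.0], -8.0)
        es = -6.0 * A + env_eff + cov @ [2.0, 1.0] + rng.normal(0, 3, n)
        res = fit_gene_environment(es, A, env, cov,
                                   levels=["<18", "18-25", ">=25"])
        # no true interaction: F-test P is just noise, cells populated
        assert res.interaction_p > 1e-4
        assert len(res.cells) == 6

    def test_two_level_env_f_equals_squared_t(self):
        rng, A, B, cov = toy_design(8)
        es = rng.normal(size=200) - 3 * A - 2 * B + 5 * A * B
        env = np.where(B == 1, "high", "low")
        gg = fit_gene_gene(es, A, B, cov)
        ge = fit_gene_environment(es, A, env, cov, levels=["low", "high"])
        assert ge.interaction_p == pytest.approx(gg.interaction_p, rel=1e-8)

    def test_null_f_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        n = 400
        for _ in range(150):
            A = rng.integers(0, 2, n).astype(float)
            env = rng.choice(["a", "b", "c"], n)
            cov = rng.normal(size=(n, 1))
            es = -5 * A + cov[:, 0] + rng.normal(size=n)
            ps.append(fit_gene_environment(es, A, env, cov,
                                           levels=["a", "b", "c"]).interaction_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_localized_effect_found_in_right_band(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(child_seed(31, s))
            n = 450
            A = rng.integers(0, 2, n).astype(float)
            env = rng.choice(["<18", "18-25", ">=25"], n)
            cov = rng.normal(size=(n, 1))
            es = rng.normal(0, 4, n) + cov[:, 0]
            es[(A == 1) & (env == "18-25")] -= 12.0  # carriers hit mid-band
            res = fit_gene_environment(es, A, env, cov,
                                       levels=["<18", "18-25", ">=25"])
            carrier = [c for c in res.cells if c.level_a == 1]
            best = min(carrier, key=lambda c: c.p)
            hits += best.level_b == "18-25"
        assert hits >= 8


class TestFamilyScans:
    def test_two_snps_single_pair_q_equals_p(self, planted_cohort):
        res = pairwise_scan(["snp00003", "snp00007"],
                            planted_cohort["panel"],
                            planted_cohort["slopes"], planted_cohort["cov"])
        assert len(res) == 1
        assert res[0].q == pytest.approx(res[0].interaction_p)

    def test_ten_snps_give_45_pairs(self, planted_cohort):
        snps = [f"snp{j:05d}" for j in range(10)]
        res = pairwise_scan(snps, planted_cohort["panel"],
                            planted_cohort["slopes"], planted_cohort["cov"])
        assert len(res) == 45

    def test_planted_synergistic_pair_attains_min_q(self):
        hits = 0
        for s in range(5):
            cfg = SimulationConfig(
                n_subjects=301, n_snps=10, maf_range=(0.25, 0.45),
                interaction_effects=[("gg", 2, 5, -25.0)],
                seed=child_seed(32, s))
            panel, pheno, cov, _ = simulate_cohort(cfg)
            slopes, _ = estimate_all_slopes(pheno)
            res = pairwise_scan(panel.snp_ids, panel, slopes, cov)
            best = min(res, key=lambda r: r.q)
            hits += {best.factor_a, best.factor_b} == {"snp00002", "snp00005"}
        assert hits >= 4

    def test_environment_family_q_within_family(self, planted_cohort):
        snps = [f"snp{j:05d}" for j in range(4)]
        res = environment_scan(snps, planted_cohort["panel"],
                               planted_cohort["slopes"], planted_cohort["cov"],
                               age_bands(planted_cohort["cov"]), "age",
                               drop_covariate="age",
                               levels=["<18", "18-25", ">=25"])
        assert len(res) == 4
        assert all(np.isfinite(r.q) for r in res)
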