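import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endoscan.association import scan
from endoscan.grs import (CARRIER, NONCARRIER, age_bands, compute_grs,
                          derive_risk_coding, endotoxin_strata,
                          grs_category_effects, grs_stratified, grs_trend)
from endoscan.slopes import estimate_all_slopes
from endoscan.synthetic import SimulationConfig, simulate_cohort

from conftest import child_seed


def coding_frame(betas):
    return pd.DataFrame({"snp_id": [f"rs{i}" for i in range(len(betas))],
                         "beta": betas})


class TestRiskCoding:
    def test_negative_beta_marks_carriers(self):
        coding = derive_risk_coding(coding_frame([-15.17]))
        assert coding["rs0"] == CARRIER

    def test_positive_beta_marks_noncarriers(self):
        coding = derive_risk_coding(coding_frame([17.21]))
        assert coding["rs0"] == NONCARRIER

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError, match="zero beta"):
            derive_risk_coding(coding_frame([0.0]))

    def test_nan_beta_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            derive_risk_coding(coding_frame([np.nan]))


class TestComputeGrs:
    def test_extreme_subjects(self, planted_cohort):
        panel = planted_cohort["panel"]
        res, _ = scan(panel, planted_cohort["slopes"], planted_cohort["cov"])
        top = res.sort_values("p").head(10)
        coding = derive_risk_coding(top)
        g = compute_grs(panel, coding)
        assert g["grs"].between(0, 10).all()

    def test_counting_matches_brute_force(self, planted_cohort):
        panel = planted_cohort["panel"].subset(snp_idx=list(range(8)))
        calls = panel.calls.copy()
        calls[::9, 2] = -1  # sprinkle missing
        from endoscan.io_formats import GenotypePanel
        holey = GenotypePanel(panel.snps, panel.subjects, calls)
        rng = np.random.default_rng(2)
        coding = {s.snp_id: (CARRIER if rng.random() < 0.5 else NONCARRIER)
                  for s in holey.snps}
        g = compute_grs(holey, coding).set_index("subject")
        from endoscan.association import encode_genotype
        codes = {s.snp_id: encode_genotype(calls[:, j], "dominant")[0]
                 for j, s in enumerate(holey.snps)}
        for i, subj in enumerate(holey.subjects):
            expect = 0
            for sid, side in coding.items():
                c = codes[sid][i]
                if np.isnan(c):
                    continue
                expect += (c == 1) if side == CARRIER else (c == 0)
            assert g.loc[subj, "grs"] == expect

    def test_snp_order_invariance(self, planted_cohort):
        panel = planted_cohort["panel"]
        coding = {"snp00001": CARRIER, "snp00004": NONCARRIER,
                  "snp00009": CARRIER}
        a = compute_grs(panel, coding)["grs"]
        b = compute_grs(panel, dict(reversed(list(coding.items()))))["grs"]
        np.testing.assert_array_equal(a, b)

    def test_flip_changes_by_nonmissing_count(self, planted_cohort):
        panel = planted_cohort["panel"]
        coding = {"snp00001": CARRIER, "snp00004": NONCARRIER}
        flipped = {"snp00001": NONCARRIER, "snp00004": NONCARRIER}
        a = compute_grs(panel, coding)
        b = compute_grs(panel, flipped)
        from endoscan.association import encode_genotype
        code, _ = encode_genotype(panel.calls[:, 1], "dominant")
        obs = ~np.isnan(code)
        # each non-missing subject's contribution maps c -> 1-c
        delta = (a["grs"] - b["grs"]).to_numpy()
        np.testing.assert_array_equal(delta[obs], 2 * code[obs] - 1)


class TestGrsTrend:
    def test_planted_linear_trend_exact(self, planted_cohort):
        panel = planted_cohort["panel"]
        cov = planted_cohort["cov"]
        coding = {f"snp{j:05d}": CARRIER for j in range(6)}
        g = compute_grs(panel, coding)
        design = cov.design_frame().loc[panel.subjects]
        es = (-3.0 * g["grs"].to_numpy()
              + 0.5 * design["height"].to_numpy())
        slopes = pd.DataFrame({"subject": panel.subjects, "es": es})
        tr = grs_trend(panel, slopes, cov, g)
        assert tr.beta == pytest.approx(-3.0, abs=1e-8)

    def test_null_p_uniform_over_seeds(self):
        ps = []
        for s in range(100):
            rng = np.random.default_rng(child_seed(41, s))
            n = 150
            g = pd.DataFrame({"subject": [f"S{i:04d}" for i in range(n)],
                              "grs": rng.integers(0, 10, n),
                              "n_missing": 0, "n_coded": 10})
            cfg = SimulationConfig(n_subjects=n, n_snps=2,
                                   seed=child_seed(42, s))
            panel, pheno, cov, _ = simulate_cohort(cfg)
            slopes, _ = estimate_all_slopes(pheno)
            ps.append(grs_trend(panel, slopes, cov, g).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_grs_rejected(self, planted_cohort):
        panel = planted_cohort["panel"]
        g = pd.DataFrame({"subject": panel.subjects, "grs": 3,
                          "n_missing": 0, "n_coded": 10})
        with pytest.raises(ValueError, match="constant"):
            grs_trend(panel, planted_cohort["slopes"],
                      planted_cohort["cov"], g)

    def test_paper_scale_cohort_gives_tiny_trend_p(self):
        effs = [(-1) ** k * (10.0 + 0.8 * k) for k in range(10)]
        cfg = SimulationConfig(n_subjects=301, n_snps=10,
                               maf_range=(0.15, 0.4),
                               snp_effects=list(enumerate(effs)),
                               seed=child_seed(43))
        panel, pheno, cov, _ = simulate_cohort(cfg)
        slopes, _ = estimate_all_slopes(pheno)
        res, _ = scan(panel, slopes, cov)
        coding = derive_risk_coding(res)
        g = compute_grs(panel, coding)
        tr = grs_trend(panel, slopes, cov, g)
        assert tr.beta < 0
        assert tr.p < 1e-10


class TestGrsStratified:
    def test_identical_trend_across_strata_zero_interaction(self, planted_cohort):
        panel = planted_cohort["panel"]
        cov = planted_cohort["cov"]
        coding = {f"snp{j:05d}": CARRIER for j in range(6)}
        g = compute_grs(panel, coding)
        rng = np.random.default_rng(3)
        es = -3.0 * g["grs"].to_numpy() + rng.normal(0, 1e-6, panel.n_subjects)
        slopes = pd.DataFrame({"subject": panel.subjects, "es": es})
        out = grs_stratified(panel, slopes, cov, g, age_bands(cov),
                             drop_covariate="age")
        for v in out["per_stratum"].values():
            if not v["flagged"]:
                assert v["beta"] == pytest.approx(-3.0, abs=1e-4)
        for b in out["interaction_betas"]:
            assert b == pytest.approx(0.0, abs=1e-4)

    def test_differential_trend_detected(self):
        hits = 0
        for s in range(5):
            cfg = SimulationConfig(n_subjects=300, n_snps=8,
                                   maf_range=(0.2, 0.45),
                                   seed=child_seed(44, s))
            panel, pheno, cov, _ = simulate_cohort(cfg)
            coding = {f"snp{j:05d}": CARRIER for j in range(8)}
            g = compute_grs(panel, coding)
            young = (cov.subjects.set_index("subject")["age"] < 25).loc[
                panel.subjects].to_numpy()
            rng = np.random.default_rng(child_seed(45, s))
            es = np.where(young, -5.0, -1.0) * g["grs"].to_numpy() \
                + rng.normal(0, 8, 300)
            slopes = pd.DataFrame({"subject": panel.subjects, "es": es})
            strata = pd.Series(np.where(young, "young", "old"),
                               index=panel.subjects)
            out = grs_stratified(panel, slopes, cov, g, strata,
                                 levels=["young", "old"])
            hits += out["interaction_p"] < 0.05
        assert hits >= 4

    def test_single_stratum_reduces_to_trend(self, planted_cohort):
        panel = planted_cohort["panel"]
        coding = {f"snp{j:05d}": CARRIER for j in range(6)}
        g = compute_grs(panel, coding)
        strata = pd.Series("all", index=panel.subjects)
        out = grs_stratified(panel, planted_cohort["slopes"],
                             planted_cohort["cov"], g, strata)
        tr = grs_trend(panel, planted_cohort["slopes"],
                       planted_cohort["cov"], g)
        st = out["per_stratum"]["all"]
        assert st["beta"] == pytest.approx(tr.beta, abs=1e-10)
        assert np.isnan(out["interaction_p"])

    def test_category_effects_monotone_shape(self, planted_cohort):
        panel = planted_cohort["panel"]
        cov = planted_cohort["cov"]
        coding = {f"snp{j:05d}": CARRIER for j in range(6)}
        g = compute_grs(panel, coding)
        es = -4.0 * g["grs"].to_numpy()
        slopes = pd.DataFrame({"subject": panel.subjects, "es": es})
        cats = grs_category_effects(panel, slopes, cov, g)
        np.testing.assert_allclose(
            cats["beta"], -4.0 * (cats["grs"] - cats["grs"].iloc[0]),
            atol=1e-6)


def test_strata_constructors(planted_cohort):
    cov = planted_cohort["cov"]
    bands = age_bands(cov)
    assert set(bands.unique()) <= {"<18", "18-25", ">=25"}
    ages = cov.subjects.set_index("subject")["age"]
    assert (bands[ages < 18] == "<18").all()
    assert (bands[(ages >= 18) & (ages < 25)] == "18-25").all()
    strata = endotoxin_strata(cov)
    mean_exp = cov.endotoxin.groupby("subject")["endotoxin"].mean()
    med = mean_exp.median()
    assert (strata[mean_exp <= med] == "low").all()
    assert (strata[mean_exp > med] == "high").all()
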