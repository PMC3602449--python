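import numpy as np
import pytest

from endoscan.slopes import estimate_all_slopes
from endoscan.synthetic import SimulationConfig, simulate_cohort


def child_seed(*path: int) -> int:
    """Deterministic sub-seed derived from a path of integers."""
    return int(np.random.default_rng(list(path)).integers(2**31))


@pytest.fixture(scope="session")
def planted_cohort():
    """One paper-sized cohort with two planted dominant effects, fitted
    slopes included; shared by scan/interaction/score tests."""
    cfg = SimulationConfig(
        n_subjects=301, n_snps=60, maf_range=(0.1, 0.4),
        snp_effects=[(3, -15.0), (7, -12.0)],
        seed=20240101,
    )
    panel, pheno, cov, truth = simulate_cohort(cfg)
    slopes, summary = estimate_all_slopes(pheno)
    return {"cfg": cfg, "panel": panel, "pheno": pheno, "cov": cov,
            "truth": truth, "slopes": slopes, "summary": summary}


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Deterministic cohort: no measurement or slope noise, one planted
    dominant effect of -15 ml/month."""
    cfg = SimulationConfig(
        n_subjects=200, n_snps=12, maf_range=(0.1, 0.4),
        snp_effects=[(2, -15.0)],
        within_subject_sd=0.0, between_subject_slope_sd=0.0,
        dropout_probs=(1.0, 1.0, 1.0, 1.0),
        seed=77,
    )
    panel, pheno, cov, truth = simulate_cohort(cfg)
    slopes, summary = estimate_all_slopes(pheno)
    return {"cfg": cfg, "panel": panel, "pheno": pheno, "cov": cov,
            "truth": truth, "slopes": slopes, "summary": summary}
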