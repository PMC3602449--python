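#!/usr/bin/env python
"""Genetic risk score over the top-10 dominant hits.

Derives each SNP's risk side from the sign of its adjusted beta, counts
risk genotypes per subject, and fits the adjusted trend of the slope
phenotype on the score — then repeats the trend within age bands and
endotoxin halves and tests the score-by-stratum interaction.
"""

from pathlib import Path

import pandas as pd

from endoscan.grs import (AGE_BAND_LEVELS, ENDOTOXIN_LEVELS, age_bands,
                          compute_grs, derive_risk_coding, endotoxin_strata,
                          grs_category_effects, grs_stratified, grs_trend)
from endoscan.io_formats import (read_covariates, read_genotype_panel,
                                 read_results_table, write_results_table)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = read_genotype_panel(ROOT / "data" / "cohort_qc.ped",
                                ROOT / "data" / "cohort_qc.map")
    slopes = read_results_table(ROOT / "slopes.tsv")
    cov = read_covariates(ROOT / "data" / "covariates.tsv",
                          ROOT / "data" / "endotoxin_visits.tsv")
    top = read_results_table(ROOT / "top10_dominant.tsv")

    coding = derive_risk_coding(top)
    grs = compute_grs(panel, coding)
    write_results_table(grs, ROOT / "grs_scores.tsv")
    dist = grs["grs"].value_counts().sort_index()
    print("score distribution:", dict(dist))

    tr = grs_trend(panel, slopes, cov, grs)
    print(f"trend: {tr.beta:.2f} ml/month per risk genotype "
          f"(SE {tr.se:.2f}), P_trend = {tr.p:.3g}, n = {tr.n}")
    cats = grs_category_effects(panel, slopes, cov, grs)
    write_results_table(cats, ROOT / "grs_category_effects.tsv")

    rows = []
    for name, strata, levels, dropped in (
            ("age", age_bands(cov), AGE_BAND_LEVELS, "age"),
            ("endotoxin", endotoxin_strata(cov), ENDOTOXIN_LEVELS,
             "log_endotoxin")):
        out = grs_stratified(panel, slopes, cov, grs, strata,
                             drop_covariate=dropped, levels=levels)
        print(f"stratified by {name}: "
              f"interaction P = {out['interaction_p']:.3g}")
        for level, st in out["per_stratum"].items():
            flag = " (flagged: too few subjects)" if st["flagged"] else ""
            print(f"  {level}: n={st['n']}, trend {st['beta']:.2f} "
                  f"(SE {st['se']:.2f}), P = {st['p']:.3g}{flag}")
            rows.append({"stratifier": name, "stratum": level, **st,
                         "interaction_p": out["interaction_p"]})
    pd.DataFrame(rows).to_csv(ROOT / "grs_stratified.tsv", sep="\t",
                              index=False, float_format="%.6g")
    print(f"wrote score tables under {ROOT}")


if __name__ == "__main__":
    main()
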