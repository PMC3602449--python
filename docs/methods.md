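# Methods

`endoscan` implements a two-stage genetic association analysis of
longitudinal lung function in an occupationally exposed cohort, plus
the quality-control, multiplicity, validation and summary machinery
that surrounds such a scan. This note records the models, the defaults
and why they were chosen, and the places where a design decision was
genuinely open.

## The two-stage association model

**Stage 1 — slope phenotype.** Each subject *i* contributes spirometry
visits (FEV₁ in ml) at months 0, 3, 12, 18. A per-subject ordinary
least squares line

  FEV₁ᵢⱼ = u₀ᵢ + ESᵢ · monthⱼ + eᵢⱼ

defines the estimated slope ESᵢ (ml/month), the derived phenotype of
everything downstream. Subjects with a single visit cannot define a
slope and are dropped with a log entry. Two-visit subjects are
retained; their line is saturated (R² = 1 by construction), which
inflates the cohort R² summary — a property of the design, not a bug.
A perfectly flat series has undefined R² (0/0) and is recorded as
missing.

**Stage 2 — per-SNP regression.** For each SNP,

  ESᵢ = α + β·Gᵢ + γ₁·heightᵢ + γ₂·ageᵢ + γ₃·FEV₁-baselineᵢ
        + γ₄·log-endotoxinᵢ + eᵢ

with G coded dominant (minor-allele carrier 0/1) or additive
(minor-allele count 0/1/2). β, its SE and the two-sided t-test P come
from the genotype coefficient. Negative β means carriers decline
faster. Under the additive model, SNPs whose minor-homozygote
frequency is ≤ 5% of non-missing calls are excluded as non-robust;
monomorphic SNPs are excluded under either model. Missing genotypes
or covariates give per-SNP complete-case fits.

The scan evaluates all SNPs through one Frisch–Waugh–Lovell
projection: genotype columns and the phenotype are residualized on the
covariates once (QR-based), after which each SNP's β, SE and t are
one-dimensional expressions. This is algebraically identical to the
per-SNP full regression — the test suite asserts equality against both
the per-SNP path and an explicit normal-equations oracle — and is what
makes permutation re-scans cheap (one matrix product per replicate
batch).

**Endotoxin covariate.** "Average level of log-transformed exposure"
admits two readings; the default is log(mean across visits), with
mean(log) behind `endotoxin_order="mean_of_log"`. The choice is
recorded in output metadata by the drivers that expose it.

**Baseline FEV₁ covariate** is the observed month-0 measurement, not
the fitted intercept u₀ᵢ — using u₀ᵢ would inject estimation noise
correlated with ESᵢ.

## Quality control

SNP filters run sequentially — non-autosomal chromosome, call rate
≤ 0.95, MAF < 0.05, Hardy–Weinberg exact P < 0.001 — and each SNP is
charged to the *first* criterion it fails, so category counts add up
to the total removed (single-pass bookkeeping). Note the boundary
asymmetry, preserved deliberately: SNP call rate removes at *≤* 0.95,
subject call rate at *<* 0.95.

The HWE test is the conditional exact test (sum of probabilities of
all heterozygote counts, given the allele counts, whose point
probability does not exceed the observed one) — the convention of
standard chip-QC toolchains, exact for the rare-variant tables where
the χ² approximation fails. It is verified against exhaustive
exact-rational enumeration for every table with up to 50 subjects.

Sample filters: call rate; then cryptic relatedness as mean
identity-by-state sharing over jointly non-missing SNPs with threshold
0.9 (a deliberate, simpler stand-in for pi-hat; duplicates and
near-duplicates sit near 1.0, unrelated subjects near 0.65–0.80 for a
common-variant panel), removing the lower-call-rate member of each
flagged pair (ties: the later subject); then principal-component
outliers at > 6 SD on any of the top 10 PCs of the standardized,
mean-imputed genotype matrix (the EIGENSTRAT convention, single pass,
without the iterative re-estimation or Tracy–Widom machinery). The
relatedness and outlier rules are conventions, not published
thresholds, and are flagged as such in the QC report.

MAF and HWE are *not* recomputed after sample filtering when the two
cascades run jointly (`run_qc`): survivor counts then reproduce
single-pass bookkeeping exactly.

## Multiplicity: permutation-based FWER and FDR

Chip SNPs are correlated through linkage disequilibrium, so Bonferroni
(0.05/m) overcounts effective tests. The calibration permutes the
*phenotype* and never the genotype columns, so the inter-SNP
correlation carries into the null. Default scheme is Freedman–Lane:
regress ES on the covariates, permute the residuals across subjects,
add back the fitted part, re-run the scan, record all null P-values
and their minimum. (Adding back the fitted part is a no-op for the
genotype t statistic — the projection removes it again — which the
implementation exploits; a raw-phenotype shuffle is available behind a
flag.)

* FWER: the per-test threshold at level α is the α-quantile (lower
  tail, inverted-CDF convention) of the min-P distribution.
* FDR: q(p) = (average per-replicate count of null P ≤ p) / #{observed
  P ≤ p}, capped at 1 and made monotone by a cumulative minimum from
  the largest p downward (no π₀ estimation).

Default `n_perm` = 1000; fewer than 100 replicates is rejected because
tail quantiles are unstable. Simulation checks: over 500 global-null
cohorts (n = 150, 100 SNPs, 500 permutations) the empirical FWER at
nominal 0.15 and the realized false-discovery proportion of q ≤ 0.10
declarations sit within 3-SE Monte-Carlo bands of their targets.

Two limiting behaviours are verified: duplicated SNPs collapse the
threshold to α (effective tests → 1), and independent SNPs approach
the Šidák level 1 − (1−α)^(1/m). The Šidák identity assumes exactly
uniform per-test P; at moderate n the exact permutation distribution
of a t statistic with a binary regressor has slightly lighter extreme
tails than the t reference, making per-test P conservative there and
pushing the min-P threshold above Šidák by O(1/n) (about +20% at
n = 150, within ~10% by n = 800). The independence-limit test
therefore runs at n = 800 with a 15% band; the FWER calibration above
is the operative guarantee at study scale.

## Bootstrap stability

A validated hit is refitted on subject-level bootstrap resamples
(covariates travel with the subject; slopes are resampled as fixed
per-subject quantities, with per-replicate slope re-estimation behind
a flag). The stability criterion: P at or below a predefined threshold
— default 0.05 divided by the number of SNPs under validation, 0.005
for 10 — in ≥ 80% of replicates. Replicates with a constant resampled
genotype or rank-deficient design count as failures; redrawing them
would bias the proportion upward.

A caution established during development and asserted in the tests:
for a *null* SNP the proportion is not the nominal size. Conditional
on a cohort, the bootstrap t recenters on that cohort's observed t, so
the proportion of replicates with P ≤ c has expectation ≈ 2Φ(−z_c/√2)
— about 5% at c = 0.005 — with a heavy right tail across cohorts
(median ≈ 0.02). It remains far below the 0.80 cutoff, which is what
the criterion uses; tests assert the median/mean bounds and
monotonicity in effect size rather than a literal 0.005.

## Interactions

Gene–gene: both parameterizations of the same linear model are fitted
on the same complete cases — the product model (covariates + A + B +
A·B; interaction P from the A·B t test, the primary single-df P) and
the joint-cell model (four genotype cells against the double-reference
cell, giving the per-cell contrasts study tables report). They are
linear reparameterizations; the tests assert the cell contrasts equal
the corresponding sums of product-model coefficients.

Gene–environment: genotype × environment-level joint cells, reference
(noncarrier, first level); the interaction P is an F test of the
genotype×level products on (levels − 1) df, which reduces exactly to
the squared-t product test for a two-level environment (asserted).
The environment-derived covariate (age, or log endotoxin) leaves the
adjustment set to avoid near-collinearity; keeping it is selectable.

Families and FDR: all C(k,2) gene–gene pairs form one
Benjamini–Hochberg family; each environment's k SNP tests form their
own family.

Age bands are <18, [18, 25), ≥25 years — the boundary 25 goes to the
upper band — and the endotoxin split is at the cohort median with ties
to the lower stratum.

## Genetic risk score

Each top SNP's risk side is the sign of its adjusted dominant β:
carriers are the risk group when β < 0, reference homozygotes when
β > 0 (β = 0 is an error, not a silent choice). The score counts risk
genotypes; a missing call contributes 0, so the score is a lower
bound, and subjects missing > 20% of coded SNPs leave the trend
models. The trend model enters the score as a single ordinal term; a
per-category parameterization supports coefficient plots. Stratified
trends drop the stratifying covariate from the within-stratum
adjustment; the score×stratum interaction comes from the product terms
of the pooled model.

Deriving the coding from the same scan that selected the top SNPs is
circular (winner's curse); in-sample trend P-values overstate
out-of-sample evidence. This is inherent to the design and documented
rather than corrected.

## Synthetic cohorts

The generator draws what the analysis assumes: independent
Hardy–Weinberg genotypes with a configurable MAF spectrum; a
two-component age mixture (54.2% young new hires ~18.4 y, 45.8% older
transfers ~33.1 y) so age-stratified analyses are meaningful; height
~ N(160, 5.5) cm, baseline FEV₁ ~ N(2630, 350) ml; endotoxin assigned
by work area (levels 60–400 EU/m³, median area 163) with ~25%
lognormal visit-to-visit wobble; true slopes = intercept + centered
covariate effects + dominant SNP effects + optional SNP×SNP and
SNP×covariate products + N(0, σ_b²); visits at months 0/3/12/18 with
staged dropout (retention defaults reproduce ~21% stopping after month
3, ~14% after month 12, ~65% completing). Linkage can be introduced
explicitly by duplicating a SNP column with a flip probability — used
to test min-P behaviour under correlation — but is otherwise absent.

Two noise scales were genuinely open and were calibrated once, by
simulation over a grid, against three cohort summaries at the default
n = 301: within-subject FEV₁ noise 100 ml and between-subject slope
noise 10 ml/month give mean/median per-subject R² of 0.64/0.75 and a
slope SD of 25 ml/month under null genetics (targets 0.63/0.73 and
~25). Genotype calls carry no missingness by default (the engineered
QC fixtures supply missingness); the slope intercept defaults to
−6.79 ml/month.

What passing tests on these cohorts do *not* show about real data:
no linkage structure (hence no realistic effective-test count), no
population stratification beyond the engineered outlier fixture, no
chip ascertainment, Gaussian measurement noise, and exposure
misclassification only through the lognormal area wobble.

The QC fixture generator is deterministic where it matters: passing
SNPs get genotype counts at the rounded Hardy–Weinberg mode (exact
test P ≈ 1, so no SNP fails by sampling accident), violating SNPs get
counts that fail their criterion with margin (all-heterozygote columns
for HWE failures — infeasible below ~25 subjects and rejected),
genotypes are then permuted within columns to destroy subject-level
structure, and subject-level violators (8% missingness, 2%-flip
near-duplicates placed after their sources, +0.4 frequency-shifted
outliers) are appended so that each filter removes exactly the
requested count.

## Numerical choices

OLS everywhere is least squares via QR/SVD (`numpy.linalg.lstsq`),
with classical covariance; statsmodels provides the F tests and BH
correction. P-values from exact (zero-residual) fits are floored at
the smallest positive float rather than reported as 0. The
genomic-control λ is median(χ²₁-quantile of 1−p) / 0.454936. Empirical
quantiles of permutation distributions use the inverted-CDF convention
(α = 1 returns the maximum). Rank-deficient designs are excluded with
a reason, never silently dropped. All randomness flows through
`numpy.random.default_rng` seeds; fixed seed means bit-identical
output.

## Problem sizes in the checks

The calibration suite runs 500 null cohorts at n = 150 × 100 SNPs ×
500 permutations, the recovery suite 200 cohorts at n = 301, the
independence limit 3 cohorts at n = 800 × 2000 permutations, and the
HWE sweep all ~23k tables to n = 50 — sizes at which the Monte-Carlo
bands quoted above are meaningful while a full run of the suite stays
in the minutes range.
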