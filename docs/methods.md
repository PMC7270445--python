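# Methods

## Scope and data model

The package analyses a pregnancy cohort in which each mother has:
covariates (age, height, pre-pregnancy weight/BMI, MUAC, geography,
outdoor-activity score, supplement use), serum 25(OH)D at two visits
(first trimester T1, <13 weeks; third trimester T3, >27 weeks; ng/mL),
genotypes at a six-SNP vitamin D panel, and a singleton newborn with
birth weight (g), birth length (cm) and head circumference (cm).

Inputs are plain text: a SNP manifest (TSV/YAML), a long-format genotype
TSV (`sample_id, rsid, allele1, allele2`; a GT-only VCF adapter is
provided), and a one-row-per-mother phenotype CSV. The manifest is the
single source of truth for allele coding; loading fails if any row lacks
an explicit risk allele. The analyzable set is the inner join of
mothers, neonates and genotyped samples; the join never fabricates
records and reports its accounting. Missing values propagate as
null — no imputation anywhere; every model is complete-case and records
the n it actually used.

## Genetic risk scores

Scores are unweighted risk-allele counts. The risk allele at each SNP is
the 25(OH)D-lowering allele; for four of the six default SNPs this
follows GWAS convention (rs12785878 G, rs2282679 C, rs6013897 A,
rs2228570 A) and is deliberately configuration, not code. Three schemes:
total (6 SNPs, 0–12), synthesis (DHCR7 + CYP2R1, 0–4), metabolism
(GC + CYP24A1 + 2×VDR, 0–8). Dichotomization cut-points are fixed:
total ≤3 vs ≥4, synthesis <2 vs ≥2, metabolism ≤3 vs ≥4.

A score is missing if any constituent genotype is missing. An optional
proportional-rescaling mode (observed sum × m/k for k called SNPs)
exists for sensitivity analyses and is off by default, since group
sizes in this design presume complete cases.

QC per SNP: minor-allele frequency over called alleles and the
asymptotic 1-df Pearson chi-square HWE test with expected counts
(p²n, 2pqn, q²n) from the observed allele frequency. The asymptotic
test (not an exact test) is used deliberately; for the cohort sizes
involved (n ≈ 183) it is standard. A monomorphic SNP returns
chi² = 0, p = 1 by convention and is flagged rather than crashing QC.

## Phenotype classification

* IOM vitamin D status: deficient < 12, insufficient 12 ≤ x < 20,
  sufficient ≥ 20 ng/mL. Half-open intervals partition [0, ∞) with no
  gap between 19.99 and 20.
* WHO newborn cut-offs: low birth weight < 2500 g, short length < 50 cm,
  small head circumference < 35 cm; labels are independent.
* WHO Asian BMI bands: underweight < 18.5; normal 18.5–23.49; overweight
  23.5–24.99; pre-obese 25–29.99; obese ≥ 30 kg/m². Bands are defined at
  two-decimal precision, so the computed BMI is rounded to 2 d.p. before
  banding (this keeps e.g. 76.8 kg / 160 cm, arithmetically
  29.999999999999996, in the obese band it belongs to).
* Change score: Δ25(OH)D = T3 − T1, signed, defined only when both
  visits are present. Category *transitions* between visits are reported
  descriptively only; the numeric delta is the analysed outcome.

## Statistical engine

* **Linear models**: OLS; SEs from the unbiased residual variance;
  two-sided t p-values. Rank-deficient designs raise an error naming
  the collinear columns. Implemented on `statsmodels.OLS`; the test
  suite verifies it against an independently written normal-equations
  oracle on random designs (1e-8 relative).
* **Logistic models**: IRLS via `statsmodels` GLM with a binomial
  family; Wald SEs/p-values. Complete separation is flagged
  (`converged=False`, detected via separation warnings or |β| > 15)
  rather than raised, so screening loops survive. Verified against the
  closed-form 2×2-table log odds ratio and SE √(1/a+1/b+1/c+1/d).
* **Multinomial outcomes** are decomposed into one-vs-reference binary
  logistic fits. This is an approximation to the joint softmax
  likelihood, adequate here because only per-contrast coefficients and
  p-values are reported; with two levels it is exact.
* **Interaction fit**: OLS with main effects, the `GRS × 25(OH)D`
  product term and covariates. The GRS enters as the continuous allele
  count by default; a 0/1 group indicator reproduces the stratified
  display. The product-term row is the reported quantity.
* **Classical tests**: Student (pooled-variance) two-sample t, paired t,
  Pearson correlation, and one-sample Kolmogorov–Smirnov against a
  normal with sample-estimated mean/SD. The KS test applies no
  Lilliefors correction — p-values are conservative — matching the
  legacy-package output this workflow descends from.
* **Bonferroni families**: threshold = α/m, stored unrounded for
  decisions with a 3-decimal display value (9 tests → 0.00556/0.006;
  18 tests → 0.00278/0.003). All tests two-sided, family α = 0.05.
* **Sample size**: n = 2(Z_α+Z_β)²S²/(U₁−U₂)² per group, plus its
  ceiling; invariant under sign flip of the difference.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the
pipeline assumes; all randomness flows from one
`numpy.random.default_rng(seed)`, so a seed fixes the cohort bit for
bit.

* **Genotypes**: each SNP i.i.d. Binomial(2, p) under HWE; default
  risk-allele frequencies (0.28, 0.39, 0.27, 0.22, 0.35, 0.18) span the
  0.18–0.39 range of the reference panel and put ~55% of mothers in the
  ≤3-allele group, matching the observed split.
* **Serum 25(OH)D**: T1 ~ N(14.00, 6.97²). T3 is the configured
  population mean 21.21 plus a deviation correlated with T1 (ρ = 0.425)
  with environmental SD 9.5, minus `beta_snp × (GRS − E[GRS])`. Centring
  the genetic term keeps the configured T3 mean as the population mean;
  the marginal T3 SD is √(9.5² + beta²·Var(GRS)) ≈ 9.9. Values are
  clipped at 0.1 ng/mL (assay floor); the induced shift in the T1 mean
  is ≈ +0.06 ng/mL, well inside calibration tolerance.
* **Calibration of `beta_snp`** (default 1.82 ng/mL per allele): chosen
  so the expected T3 contrast between the dichotomized groups equals
  4.61 ng/mL, the reference contrast (23.35 − 18.74). Under the default
  frequencies E[GRS | ≥4] − E[GRS | ≤3] = 2.531, and 4.61/2.531 = 1.82.
  This is a calibration to a printed group difference, not a per-allele
  effect estimate. The genetic effect is placed on T3 (and hence the
  change score) but not T1, mirroring the finding that the association
  appears late in pregnancy; a T1 effect is configurable for power
  studies.
* **Outcomes**: birth weight ~ N(3204.87, 494.99²) g, length
  ~ N(48.56, 2.87²) cm; head circumference is N(33.89, 2.52²) plus
  `gamma_interaction × (GRS − E[GRS]) × (T3 − 21.21)`. The default
  γ = 0.08 cm per (allele × ng/mL) embeds the reported study condition;
  null simulations set it to 0. Maternal covariates and the per-visit
  series (systolic BP, body weight, MUAC, haemoglobin) are normal draws
  at the reference cohort's means/SDs with within-mother correlation for
  the paired comparisons.
* **Flow**: of `n_enrolled` (default 239), `dropout_n` (53) women are
  dropped uniformly at random before delivery and `low_dna_n` (3)
  completers are excluded for low DNA yield, leaving 183 analyzable
  pairs. `missing_rate` (default 0) adds per-visit serum missingness.

What the generator does **not** emulate: seasonality and sun-exposure
physiology, assay error structure beyond additive noise, main effects of
covariates on outcomes, linkage disequilibrium between SNPs, and any
confounding between genotype and environment. Tests passing on
synthetic cohorts therefore demonstrate correctness of the estimators
and pipeline under the assumed model — not robustness to the
misspecifications real cohorts carry.

The source text for the flow is internally inconsistent (239 enrolled
with 53 dropouts in the text; 276 with 90 in the flow-diagram caption);
the generator's defaults follow the 239 → 186 → 183 accounting and the
discrepancy is noted here rather than resolved.

## Pipeline stages and adjustment sets

Each stage reproduces one published-table layout. Covariate adjustment
sets are per-stage configuration defaults copied from the respective
table footnotes and mapped to generated columns; the pipeline never
unifies them:

| stage | adjustment set |
|---|---|
| status → anthropometry | age, pre-pregnancy BMI, preterm (GA < 37 wk), outdoor activity, supplements |
| GRS association | age, pre-pregnancy BMI, supplements, outdoor activity, geography |
| interaction | age, pre-pregnancy BMI, supplements, GA at birth, infant sex |
| per-SNP | as GRS association |

The status→anthropometry stage groups by **third-trimester** status (the
published per-category ns match the T3 distribution) and emits both a
GLM partial-F p-value (headline) and companion logistic Wald p-values
for the binary adverse labels. The association stage emits exactly 9
rows and the interaction stage exactly 18, matching the declared test
families; the interaction stage also writes the stratified display
(mean T3 25(OH)D by total-GRS group within head-circumference strata).
The per-SNP stage fits dominant-model contrasts (carriers vs
non-carriers) for T1, T3 and the change score.

`run_all` writes every report as TSV plus a JSON manifest (package
version, seed, config hash, flow accounting, per-stage row counts) and
is byte-deterministic given seed and inputs. Excluded participants are
logged with reasons.

## Numerical choices and degenerate inputs

Ties at classification boundaries go to the upper category (12 →
insufficient, 20 → sufficient, 2500 g/50 cm/35 cm → normal). Zero
variance in a t test or correlation raises, except identical groups
(t = 0, p = 1). Bonferroni decisions use the unrounded threshold.
Logistic convergence: max 100 IRLS iterations, tolerance 1e-8.
Problem sizes in the test and acceptance suites: n = 183 (default
cohort) for pipeline checks, n = 5000 for parameter recovery,
n = 20,000 for generator calibration, and 500 replicates at n = 200 for
type-I-error calibration.

## Known limitations

* The one-vs-reference multinomial decomposition is not the joint MLE.
* The KS normality p-value ignores parameter estimation (no Lilliefors
  correction).
* Dominant-model and dichotomized-GRS analyses lose information relative
  to additive coding; they are provided because the reporting layout
  requires them.
* The generator's covariates are independent of genotype and serum
  levels, so adjusted and unadjusted estimates coincide in expectation
  on synthetic data; adjustment machinery is exercised, not stressed.
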