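# vdgrs — vitamin D genetic risk scores for pregnancy cohorts

`vdgrs` is a Python library for the genetic-epidemiology workflow that links
maternal vitamin D status to newborn anthropometry through a small panel of
vitamin D pathway variants. It is aimed at epidemiologists and statistical
geneticists analysing pregnancy cohorts with per-trimester serum
25-hydroxyvitamin D [25(OH)D] measurements and genotypes at candidate SNPs.

## The model

The core quantity is an **unweighted genetic risk score**: for mother *i*
over a panel of *m* biallelic SNPs,

```
GRS_i = Σ_j  c_ij,   c_ij ∈ {0, 1, 2}
```

where `c_ij` counts copies of the 25(OH)D-*lowering* allele at SNP *j*. The
bundled six-SNP panel splits into a synthesis sub-score (DHCR7 rs12785878,
CYP2R1 rs12794714) and a metabolism sub-score (GC rs2282679, CYP24A1
rs6013897, VDR rs2228570/FokI and rs7975232/ApaI), so
`GRS = GRS_synthesis + GRS_metabolism` for every complete profile. Scores
are dichotomized at fixed cut-points (total ≤3 vs ≥4; synthesis <2 vs ≥2;
metabolism ≤3 vs ≥4) for group comparisons.

Around the score the library provides:

* per-SNP QC — minor-allele frequency and the 1-df Pearson chi-square test
  of Hardy–Weinberg equilibrium from observed genotype counts;
* deterministic phenotype classification — IOM vitamin D status
  (deficient <12, insufficient 12–<20, sufficient ≥20 ng/mL), WHO newborn
  cut-offs (<2500 g, <50 cm, <35 cm) and WHO Asian BMI bands;
* covariate-adjusted association models — OLS with t-based p-values,
  logistic regression by IRLS, one-vs-reference multinomial decomposition,
  and gene–environment interaction fits with a `GRS × 25(OH)D` product term;
* Bonferroni test families — the 9-test association family (threshold
  0.05/9, displayed 0.006) and the 18-test interaction family (0.05/18,
  displayed 0.003);
* the two-group sample-size formula `n = 2(Z_α+Z_β)² S² / (U₁−U₂)²`;
* a **seeded synthetic cohort generator** reproducing the study design —
  HWE genotypes, correlated T1/T3 serum levels with a per-allele T3
  decrement, a configurable head-circumference interaction, and the
  enrolment → dropout → low-DNA exclusion flow (239 → 186 → 183).

## Worked example

```python
from vdgrs import GeneratorConfig, generate, stage_grs_association

dataset = generate(GeneratorConfig(seed=3))
print(dataset.accounting)
report = stage_grs_association(dataset)
print(report[["scheme", "outcome", "mean_low", "mean_high", "p"]].round(2))
```

prints

```
{'enrolled': 239, 'dropped': 53, 'completed': 186, 'low_dna_excluded': 3, 'analyzable': 183}
    scheme           outcome   mean_low  mean_high     p
      vitd        25(OH)D T1      13.41      13.37  0.71
      vitd        25(OH)D T3      21.96      18.83  0.03
      vitd change in 25(OH)D       8.55       5.46  0.03
...
```

Reading: of 239 enrolled women, 183 mother–infant pairs are analyzable.
Mothers carrying ≥4 risk alleles have third-trimester 25(OH)D about
3 ng/mL lower than those with ≤3 alleles (covariate-adjusted p = 0.03),
while first-trimester levels do not differ — the genetic signal appears
late in pregnancy, as the generator encodes. Neither p-value survives the
9-test Bonferroni threshold of 0.006 at this sample size.

The `examples/` directory holds one short script per capability
(simulation, GRS + QC, association, interaction, power/classification);
each prints its results with a line of interpretation. A thin CLI mirrors
the stages:

```bash
vdgrs simulate --seed 3 --out cohort/
vdgrs associate --phenotypes cohort/phenotypes.csv --genotypes cohort/genotypes.tsv
vdgrs run-all --seed 3 --out run/
vdgrs sample-size --sd 18.5 --diff 13.08
```

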