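# polyrisk

Case-control SNP association and multiplicative genetic risk score (GRS)
analysis for candidate-SNP replication studies, with a built-in cohort
simulator. It is written for statistical geneticists who want a tested,
scriptable version of the classic two-stage design: confirm GWAS-reported
risk SNPs in a new population on a discovery half of the cohort, then ask
whether their *cumulative* effect discriminates cases from controls on an
independent testing half — and whether that signal is independent of the
strongest known locus (APOE, for sporadic Alzheimer's disease).

## The analysis

Given a cohort of cases and controls genotyped at candidate SNPs (dosage
`g ∈ {0,1,2}` counts of the reported risk allele):

1. **Quality control.** Subjects with genotype missing rate > 20% are
   removed; then SNPs with zero calls, missing rate > 5%, minor allele
   frequency < 0.01 in either arm, or Hardy-Weinberg exact-test *P* < 0.001
   among controls.
2. **Discovery association.** On a random stratified half, each SNP is
   tested by additive-model logistic regression
   `logit P(case) = β₀ + β₁ g + covariates` (sex + age, and sex + age +
   APOE ε4 carriage), reporting the allelic odds ratio `OR = exp(β₁)` with
   Wald 95% CI.
3. **LD screen.** r² between each significant SNP and the biallelically
   recoded APOE locus (ε2/ε3 vs ε4), from unphased genotypes via EM
   haplotype-frequency estimation; `r² ≥ 0.2` marks an APOE tag.
4. **Risk score.** Pharoah-style: genotypic ORs `(1, OR, OR²)` under a
   multiplicative model are divided by the population-mean risk
   `μ = Σ_g f_g·OR^g` under reference genotype frequencies `f_g`, so each
   genotype's relative risk averages to exactly 1; the GRS is the product
   over SNPs. `GRS = 1.0` means average population risk. The *modified*
   GRS drops SNPs not independent of APOE (lost significance under APOE
   adjustment, or flagged by the LD screen).
5. **Evaluation** (testing half only): Wilcoxon rank-sum association of
   GRS with status, Mann-Whitney AUC (ties count ½), and the DeLong
   placement-value test comparing the combined (GRS + APOE) marker with
   APOE alone — all midrank-safe, since a 3-SNP score takes only 27 values.

The simulator draws controls at Hardy-Weinberg equilibrium and cases from
the tilted distribution `f_g·OR^g / μ`, builds an APOE locus with a
configurable carrier OR and tag SNPs at exact target r², and ships with a
30-SNP default panel at realistic frequencies and effect sizes, so every
stage is testable without access to subject-level data.

## Worked example

```
python examples/01_simulate_and_qc.py
```

```
raw cohort: 1285 subjects x 33 SNPs
after subject QC (missing rate > 20% removed): 1210 subjects (459 cases / 751 controls), 75 removed
after SNP QC: 30 SNPs retained
  removed rs10838725: genotyping_failure
  removed rs7274581: maf
  removed rs12989701: maf
```

The fixture is built so QC has real work to do: 75 subjects exceed the
missing-rate cutoff and three SNPs fail (one assay failure, two too rare).

```
python examples/05_full_pipeline.py
```

```
testing-set evaluation (1.0 = population-average risk):
       score         stratum  n_cases  n_controls  median_cases  median_controls  wilcoxon_p   auc
    grs_full          pooled      230         376         1.080            0.744       0.000 0.665
    ...
grs_modified          pooled      230         376         1.286            0.812       0.000 0.587

DeLong paired comparison, combined (modified GRS + APOE) vs APOE alone: AUC 0.67 vs 0.62, z = 3.71, two-sided P = 0.0002
```

Cases carry systematically higher scores than controls (medians 1.08 vs
0.74); the modified score — stripped of everything APOE explains — still
discriminates (AUC 0.59), and adding it to APOE improves on APOE alone
(AUC 0.67 vs 0.62, DeLong *P* = 0.0002).

The other examples show the discovery scan (`02`), the EM LD screen
against APOE (`03`), and the risk-table construction (`04`). A thin CLI
mirrors the stages (`polyrisk simulate | qc | split | assoc | ld | grs |
evaluate | run-all`).

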