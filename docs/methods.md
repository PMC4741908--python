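# Methods

## Data model

A cohort is subjects × variants with a risk-allele dosage matrix
(0/1/2, NaN missing). Dosages are oriented to the *reported* risk allele
of each SNP, so estimated ORs are directly comparable in sign to the
source GWAS; no strand flipping is attempted, and strand-ambiguous A/T,
C/G SNPs only trigger a logged warning — resolving them is the caller's
job. Age carries the usual case-control convention for late-onset
disease studies: age at onset for cases, age at examination for controls.
The two conventions are mixed deliberately in the covariate (it is how
frequency-matched studies of this design adjust), and the package
preserves that convention rather than "fixing" it.

Supported formats: a three-file TSV layout (phenotypes, variants,
subjects × SNPs dosage table, `NA` missing) and PLINK pedigree text
(`.ped`/`.map`, `0 0` missing). The `.map` file cannot carry gene labels
or allele orientation, so the variant TSV is always the orientation
source; round-tripping either dialect reproduces the dataset exactly.
Binary PLINK, VCF writing, imputation dosages and multi-allelic variants
are out of scope.

## Quality control

Subject filter first (missing rate strictly > 0.20), then SNP filters in
a fixed precedence for reporting: genotyping failure (zero calls),
missing rate > 0.05, MAF < 0.01 *in either arm*, Hardy-Weinberg exact
*P* < 0.001 among controls. All thresholds are strict inequalities in the
removal direction; the retained set is order-independent even though the
reported reason is not. HWE uses the exact conditional test (sum of
probabilities of heterozygote counts no more probable than observed,
given allele counts) computed by the standard stable recurrence — the
field default, and the right behaviour near MAF 0.01 where the chi-square
approximation misbehaves. The test is conservative: its realized size at
the 0.001 level is well below nominal, which the suite checks by
simulation.

## Association

Per SNP, maximum-likelihood logistic regression of status on dosage plus
covariates (Newton, tolerance 1e-8 on the log-likelihood, ≤ 100
iterations, via statsmodels). The APOE adjustment is the binary ε4
carrier indicator, not allele count. Wald CIs and p-values are reported
because the OR (95% CI) presentation derives from the same statistic;
no multiple-testing correction is applied (candidate-SNP replication
convention: α = 0.05 per SNP). Missing dosage or covariates cause
listwise deletion per SNP; covariates constant across analyzed subjects
are dropped (they are collinear with the intercept). Separation is
detected by |β| > 15 or non-convergence and returned as a *flagged*
result, never a silent NaN; monomorphic SNPs are an error.

## LD estimation

Two-locus haplotype frequencies from unphased genotypes by EM (Hill gene
counting): only double heterozygotes are phase-ambiguous, and each
iteration apportions them between the cis and trans resolutions by the
current haplotype-frequency products. Initialization at linkage
equilibrium; convergence at 1e-10 maximum frequency change; ≤ 1000
iterations; subjects missing either locus dropped pairwise. D' is
reported as |D'| since only r² is consumed downstream. With no double
heterozygotes the first M-step equals the closed-form haplotype count.
The APOE locus enters as ε4-allele dosage (ε2 and ε3 collapsed), making
SNP-vs-APOE LD an ordinary two-locus problem. The screen flags
r² ≥ threshold (inclusive), 0.2 by default — the usual tag-SNP cutoff.

## Genetic risk score

Pharoah construction per SNP: allelic OR from the *discovery* fit
(sex + age model — the score is built before any APOE consideration),
genotypic ORs (1, OR, OR²), normalization by μ = Σ f_g·OR^g under
reference genotype frequencies, so Σ f_g·r_g = 1 identically and the
expected GRS is 1 for any number of independent SNPs. The reference
frequency table stands in for an external reference panel; when none is
supplied the pipeline expands discovery control-arm allele frequencies
under HWE (logged). A missing genotype contributes factor 1.0 — the
population-average risk — which keeps E[GRS] = 1 and avoids dropping
subjects; the count of imputed SNPs is kept per subject. Scores are
reported on the natural multiplicative scale. The modified score keeps
only discovery-significant SNPs that stay significant under APOE
adjustment *and* are not LD-flagged against APOE. Log-additive (weighted
sum) scores and winner's-curse shrinkage of discovery ORs are
deliberately out of scope.

## Evaluation

All discrimination statistics use midrank/half-tie conventions, which is
mandatory here: a 3-SNP multiplicative score takes ≤ 27 distinct values,
so case and control medians can coincide while the rank test is still
highly significant. Wilcoxon rank-sum uses exact enumeration when the
combined n ≤ 20 and there are no ties, otherwise a normal approximation
with tie correction and a continuity correction applied toward the null
(identical samples give z = 0, p = 1 exactly; fully tied samples give
p = 1 rather than 0/0). AUC is the normalized Mann-Whitney U. Paired
AUCs are compared by the DeLong placement-value covariance estimator;
a zero-variance difference with equal AUCs compares equal (p = 1), with
unequal AUCs it is returned flagged degenerate. The combined
GRS + APOE marker is the linear predictor of a logistic fit of status on
log-GRS + ε4 indicator on the evaluation set itself — the conventional
way ROC overlays combine a new score with an established marker; an
out-of-sample combination rule would need a third data split and is a
recognized open choice. The stratified report (pooled, ε4 carriers,
non-carriers) keeps degenerate strata as flagged rows.

## Synthetic cohorts

The generator emulates a frequency-matched two-arm cohort: controls at
HWE(p) per SNP; cases from the tilted genotype distribution
f_g·OR^g / Σ f_h·OR^h — the rare-disease reading of the multiplicative
model, which makes the configured OR the exact expected case-control OR
at O(n) cost, instead of simulating a whole population with a prevalence.
The APOE block is built at the haplotype level: ε4 alleles at frequency q
(0.106 by default, giving ~20% carriers in controls), a carrier OR of 2.8
(lifting cases to ~41% carriage), and tag SNPs whose (ε4, risk-allele)
haplotype frequencies solve D = √(r²·q(1−q)p(1−p)) for a target r² —
0.48 for the strong tag rs2075650, 0.18/0.12 for two weak tags whose
marginal association evaporates under APOE adjustment. Unattainable r²
targets error with the bound. Case APOE genotypes are tilted by carrier
status; tag alleles are then drawn per haplotype conditional on the ε4
state, which leaves the tag-given-APOE law untouched (the tilt acts only
through APOE). All other SNPs are in linkage equilibrium — the analysis
is marginal per SNP, so inter-SNP LD is out of model. Covariates: sex
Bernoulli(0.52) in both arms (frequency matching), age normal with
arm-specific means/SDs (68.5 ± 9.7 onset for cases, 72.7 ± 5.9
examination for controls), MMSE normal (14.7 ± 6.6 vs 25.1 ± 3.5,
clipped to 0–30), genotype calls missing independently (1% default).
The default panel is 30 candidate SNPs at realistic frequencies with
three directly causal SNPs (ORs 1.95, 1.60, 1.32) plus the three APOE
tags; everything else is null.

What the simulator does *not* emulate: population stratification,
genotyping batch effects, inter-SNP LD beyond the APOE block,
age-dependent penetrance, or selection effects in recruitment. Tests
passing on synthetic cohorts therefore demonstrate the statistical
machinery is correct under the stated model, not that any particular
real-world cohort satisfies that model.

### The QC fixture

`make_qc_fixture` produces a 1285-subject (515 cases / 770 controls),
33-SNP cohort whose QC outcome is part of its contract: exactly 56 cases
and 19 controls above the 20% missing-rate cutoff (nine extra masked
calls each on top of a 0.5% base rate), one zero-call SNP, two SNPs with
a handful of planted heterozygous carriers (MAF ≈ 0.005 in both arms),
and 30 SNPs that pass everything. Clean-SNP frequencies are kept ≥ 0.03
so no passing SNP sits near the 0.01 MAF boundary, and candidate draws
are verified against the QC filters and redrawn from the next
seed-derived substream in the rare event sampling noise lands a clean SNP
on the wrong side of a threshold — the fixture is defined by its outcome,
so any seed yields the same retention counts (1210 subjects, 30 SNPs)
deterministically.

### Analytic cross-check

For independent SNPs with modest effects the log risk score is
approximately normal in each arm, giving AUC ≈ Φ(√(Λ/2)) with
Λ = Σ (ln OR)²·2p(1−p). Exact enumeration over joint genotypes puts this
within ~0.01 of the true AUC for ORs ≤ 2 and frequencies away from the
extremes; the suite checks the simulated score against it at n = 20 000
within ±0.015.

## Numerical choices and problem sizes

- HWE p-values carry a 1e-12 relative slack when summing "no more
  probable" configurations so float ties are included; the suite verifies
  exhaustive agreement with log-factorial enumeration for every genotype
  configuration up to 200 diploids.
- The discovery/testing split uses floor(fraction × n) per case/control
  stratum after a seeded shuffle, so each stratum deviates from the
  target fraction by < 1 subject and the two parts partition the cohort.
- Calibration suites run 1000 null replicates (Wald, Wilcoxon, DeLong
  sizes at the 5% level) and 500 effect replicates (CI coverage at
  discovery-set sample sizes, n = 232 + 373); simulator cross-checks use
  10 000 subjects per arm. These sizes give binomial/Monte-Carlo noise
  comfortably inside the asserted bands while keeping the suite quick.
- Everything that draws random numbers takes an explicit seed
  (`numpy.random.default_rng`); identical configs give bit-identical
  datasets and byte-identical pipeline reports.

## Known limitations

- The carrier-OR parameterization of APOE ignores an ε4 dose effect
  (ε4/ε4 vs ε3/ε4), matching the binary-carrier adjustment used in the
  analysis but understating APOE's full gradient.
- Discovery ORs enter the risk table unshrunk; with marginal power the
  score inherits winner's-curse inflation, visible as full-score AUCs on
  simulated data slightly above the closed-form prediction for the true
  ORs.
- The combined GRS + APOE marker is fitted on the evaluation set (see
  above), so its AUC is mildly optimistic; the DeLong comparison is still
  valid as a paired in-sample contrast.
- The Wilcoxon exact path requires tie-free data; heavily tied small
  samples fall back to the tie-corrected normal approximation.
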