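# Methods

This note documents the statistical models implemented in `panelgwas`,
the conventions chosen where several defensible options exist, and what
the synthetic-data generator does and does not emulate.

## Data model

Genotypes are unphased biallelic calls stored as counts (0/1/2, `NaN`
missing) of a designated *count allele* per SNP — by default the
cohort-minor allele, so reported allele frequencies are MAFs.
Positions are 1-based; no strand flipping happens at load time, and
missing codes are fixed per dialect (`0 0` in PED, `NA` in the tabular
matrix); any other code is rejected rather than coerced. Phenotypes
carry BMI (kg/m²), age (years), sex, cohort and a type-2-diabetes flag;
the obesity indicator is always *derived* as BMI ≥ 30 kg/m² and never
stored independently.

## Quality control

Individuals are filtered before SNPs (both at 95% call rate); the
order matters only through borderline cases and re-running QC on its
output is a no-op. SNP filters, in order of reported precedence:
call rate < 95%, monomorphic, MAF < 1%, exact Hardy-Weinberg p < 0.001.

The HWE test is the exact conditional test: given the observed allele
totals, the p-value sums the probabilities of all heterozygote counts
whose conditional probability does not exceed the observed one.
Probabilities are computed by the standard ratio recurrence in log
space, which is numerically stable to sample sizes far beyond those
used here; the test suite checks agreement with direct enumeration to
1e-12. The asymptotic chi-square test was deliberately not used: at
MAFs near 1% and p-value thresholds of 1e-3 its type-I error is
unreliable. For X-linked SNPs HWE is computed in females only
(hemizygous males have no heterozygote class) and allele frequencies
count males as single-allele contributions. The "controls" HWE column
reports the non-obese subset; with obesity as the outcome that is the
natural control set, but any other definition would only change a
reported diagnostic, not a filter.

## Additive association

Each SNP is tested by OLS of BMI on the allele count plus age and a
female indicator (optionally the diabetes flag; the pooled analysis
adds a cohort indicator by default — dropping it leaves the simulated
results materially unchanged, and both variants are exposed). Fits use
complete cases per SNP, so the per-SNP N varies with missingness; no
imputation is done for association. p-values are two-sided from the t
distribution with residual degrees of freedom, not the normal, since
cohort sizes are finite. X-linked male genotypes are coded 0/1 by
default with a 0/2 switch (`StudyConfig.x_male_coding`); the additive
effect is per stored count unit.

SNP×SNP interactions use the product-term model
`y ~ g1 + g2 + g1·g2 + covariates`, reporting the product coefficient
and covariate-adjusted means over the 3×3 joint-genotype grid (empty
cells reported as undefined, the fit proceeds).

Family-wise error is controlled by Bonferroni over the panel's
independent tests (26 tags), reported to 3 significant figures
(0.05/26 → 0.00192).

## Haplotypes and LD

Haplotype frequencies over blocks of at most 8 SNPs (256 haplotypes,
covering the largest gene panel here) are estimated by EM from
unphased genotypes: the E-step distributes each individual over all
compatible ordered haplotype pairs proportionally to frequency
products; the M-step re-estimates frequencies from expected counts.
Initialization is uniform over haplotypes compatible with at least one
individual; iteration stops when the L1 frequency change falls below
1e-8 (cap 1000 iterations; non-convergence is flagged, not raised).
The log-likelihood is asserted non-decreasing at every iteration.
Missing sites expand an individual's compatible set (summed in the
E-step) rather than dropping the individual; individuals missing more
than half the block are dropped and counted. Haplotype dosages are
posterior-expected copies and always sum to 2 per individual.

r² between two SNPs is D²/(p_A p_a p_B p_b) with D from the two-SNP
EM solution on shared complete cases. Blocks are maximal runs of
position-consecutive SNPs with *all* pairwise r² at or above a
threshold (default 0.8). This run rule replaces confidence-interval
(D'-based) block detection on purpose: the threshold is the only
block criterion stated for this panel, and the run rule is
deterministic and testable. Tags are selected greedily — repeatedly
take the SNP covering the most uncovered SNPs at r² ≥ threshold, ties
to the lower position; on blocks of ≤8 SNPs the greedy solution is
verified against exhaustive minimum cover in the tests. Haplotype
association is one-vs-rest regression of BMI on each haplotype's
expected dosage (frequency floor 1%), mirroring per-haplotype
reporting; no global joint test is attempted.

## Meta-analysis

Effect alleles are harmonized per SNP before pooling: identical labels
pass; labels swapped within the SNP's known allele pair flip the sign
of the second study — unless the pair is strand-ambiguous (A/T, C/G),
which is excluded as `ambiguous_strand`; labels not forming the known
pair are excluded as `allele_mismatch`. With the bundled published
inputs exactly two SNPs (rs4712652, rs1424233) are excluded this way:
their panel records carry the assay-strand allele pair, which is
irreconcilable with the printed effect-allele labels.

Fixed-effect pooling is inverse-variance (weights 1/SE²). Random
effects use the DerSimonian-Laird moment estimator
tau² = max(0, (Q − df)/(S1 − S2/S1)); when Q ≤ df the random-effects
output coincides exactly with the fixed-effect one, which the code
guarantees structurally (tau² truncation) rather than numerically.
Pooled p-values use the normal approximation, consistent with the
printed tables. Heterogeneity is Cochran's Q (chi-square, k−1 df) and
I² = max(0, (Q−df)/Q)·100. Reproduction of the published pooled values
from the printed per-cohort inputs is expected only to ±0.01 on betas
and ±1.5 points on I², because the printed SEs carry two decimals.

## Weighted genetic risk score

Score SNPs are the tag SNPs whose beta is positive in both cohorts
*and* the pooled analysis (labels harmonized to the pooled effect
allele first). Weights default to the pooled betas — the selection rule
guarantees they are positive — since the source analysis does not say
which effect sizes weighted its score; per-cohort or literature weights
can be passed explicitly. Each individual's score is
`round(Σ_j w_j g_ij / mean(w))`, rounding ties away from zero; with
equal weights the score reduces to the plain risk-allele count.
Missing genotypes are imputed as twice the cohort risk-allele
frequency so every individual is scored (`grs_missing="drop"` gives
the complete-case alternative).

Quintiles are cut on the integer score at the 20/40/60/80 percentiles
with ties assigned to the lower quintile (exact 20% cuts are impossible
on an integer score; collapsed quintiles are flagged). Adjusted
quintile means come from OLS of BMI on quintile indicators plus
centered age and sex, so each indicator coefficient is the adjusted
mean at sample-mean covariates, with CIs from the coefficient
covariance. AUC is the Mann-Whitney probability computed from midranks
(ties count 1/2). Histogram-style summaries pool scores ≤2 and ≥6 at
the extremes.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes:
Hardy-Weinberg genotypes (or two haplotype draws from an LD pool), a
linear additive BMI model with Gaussian residuals, ages from a normal
truncated to [18, 90], Bernoulli sex and diabetes, and
missing-completely-at-random calls applied after phenotype generation.
Cohort targets (n, BMI mean/SD, age, sex ratio, diabetes prevalence),
per-SNP allele frequencies and per-allele effects, and per-SNP call
rates all come from the bundled published tables. The intercept and
residual SD are solved analytically from the target BMI mean and SD
after subtracting the covariate and genetic moments (the residual
variance is floored at 0.25 (kg/m²)² for pathological configurations).
Where the tag-SNP table and the panel table disagree on a MAF (the
panel's MAF column is internally inconsistent for several FTO SNPs),
the generator uses the tag-SNP table's effect-allele frequencies,
which match reference European frequencies.

Age and sex effects on BMI are generator conventions, not published
values: 0.04 kg/m² per year and +0.8 kg/m² for female sex, chosen as
plausible epidemiological magnitudes and absorbed into the calibration
so the marginal BMI distribution still hits its targets.

LD pools are constructed exactly for two SNPs (analytic D from the
target r²) and via a Gaussian copula for larger blocks: per-pair
latent correlations are calibrated by root-finding so each pairwise
r² is matched, haplotype probabilities are multivariate-normal orthant
probabilities, and realized r² is verified within 0.02 of target.
Infeasible targets (r² above D_max²/(p_A p_a p_B p_b), or a latent
matrix that is not positive semidefinite) raise an error naming the
bound. All pool associations are taken positive.

The generator does **not** emulate population stratification or
admixture, genotyping error (beyond MCAR missingness), informative
missingness, age-genotype interactions, or the lipid/glucose
phenotypes of the source populations. Passing tests therefore
demonstrate correctness of the statistical machinery under the
assumed model, not robustness to confounding present in real cohorts;
the published real-data statistics (per-cohort betas, correlations,
AUCs) are treated as parameter-recovery targets, never as values to
reproduce.

## Test and acceptance design

Every core statistic is checked against an independent brute-force
oracle on small instances: HWE against direct enumeration, OLS against
explicit normal equations, EM against a 0.01-step likelihood grid over
the 4-haplotype simplex (a finer grid is computationally pointless:
the check is that EM's likelihood is at least the grid optimum),
DerSimonian-Laird against rational-arithmetic evaluation and against
R's `metafor`, and AUC against case-control pair enumeration.

Simulation-based checks use these problem sizes: CI coverage of the
largest published effect over 200 replicates at n=848; null type-I
error over 500 replicates of a 6-SNP panel at n=400 (3000 tests);
score evaluation over 20 two-cohort studies (n=2294 each) generated
with the published pooled effects for the six score SNPs. Under those
pooled effects the quintile gradient is modest relative to sampling
noise, so strict per-replicate monotonicity of all five adjusted means
is not a reliable event (it occurs in roughly a third of replicates);
the monotonicity check is therefore made on the replicate-averaged
adjusted means, together with a positive Q5−Q1 difference in nearly
every replicate, and the score's incremental R² for BMI is verified to
average below 0.01.

## Known limitations

* EM blocks are capped at 8 SNPs; larger blocks must be split or
  tagged first.
* Only two-cohort meta-analysis is orchestrated by the pipeline (the
  pooling functions themselves accept any number of studies).
* The greedy tag rule and the r²-run block rule are stated
  conventions; no claim is made that they reproduce the tag
  assignments of other software.
* Dominant/recessive genetic models, logistic obesity models and
  imputation are out of scope.
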