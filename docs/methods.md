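# Methods

## Scope and data model

The package analyses biallelic autosomal SNP genotypes for a binary
case-control phenotype. Genotypes are minor-allele dosage codes (0/1/2,
−1 for missing) in a samples × SNPs matrix (`GenotypeDataset`); the
minor allele is the less frequent allele among all non-missing calls in
the input file, ties broken lexicographically, following the PLINK text
convention. Phenotype and covariates (age in years, sex, education in
years, BMI in kg/m², smoking history, APOE e4 carrier flag, stage,
matching identifiers) travel in a `SampleTable`.

## Quality control

Filters run in a fixed order and their tallies reconcile exactly:
(1) non-autosomal SNPs; (2) samples with genotyping success rate < 0.90;
(3) SNPs with call rate < 0.98; (4) SNPs with MAF < 0.05; (5) SNPs whose
Hardy-Weinberg exact-test P among controls is < 1e-4.

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count follows a known discrete distribution, and the
two-sided P sums the probabilities of all configurations no more
probable than the observed one. Probabilities are computed with the
stable ratio recurrence over heterozygote counts, anchored in the middle
of the support; the test is validated against exact-rational enumeration
for every configuration with total ≤ 60 and on random configurations up
to total 200. A chi-square variant exists for comparison only.

The MAF filter uses **all samples** by default (`maf_controls_only`
switches it): the QC criteria name controls explicitly only for the HWE
test, and a controls-only MAF in a small matched training set (39
controls = 78 alleles, binomial SE ≈ 0.03, plus carrier depletion in
matched controls) would remove genuinely common risk markers.

## Performance metrics and selection

Each SNP is a dominant-model test (positive = dosage ≥ 1; missing
excluded pairwise). The panel comprises sensitivity, specificity, Youden
index, PPV, NPV, diagnostic odds ratio (flagged infinite when FP·FN = 0
and undefined when TP·TN = 0 too), accuracy, net sensitivity and net
specificity of parallel combination with the APOE-e4 carrier flag, and
the AUC of a logistic model containing the SNP plus forced covariates
(age, sex, education, APOE e4). The per-SNP AUC definition is a
reconstruction — the covariate-dominated values it produces (all
≈ 0.86–0.89 across candidates) match the reported pattern, but the exact
model behind the published per-SNP AUC column is not stated anywhere.

**Metric-count selection.** Within a candidate pool, a SNP scores one
count per metric in which it attains the pool maximum (ties all count;
values are rounded to 6 decimals first so float noise cannot manufacture
a unique maximum; a SNP with an undefined metric sits that comparison
out). Ranking is by count, then mean metric rank, then AUC, then
P-value, then SNP id. The pool defaults to the top 50 SNPs by allelic
chi-square P-value (ties kept): comparing metric maxima over all
genome-wide SNPs degenerates, because among thousands of null markers
chance tables (e.g. zero carrier controls → PPV = 1, specificity ≈ 1,
DOR = ∞) monopolise the maxima. Restricting the comparison to
association-supported candidates mirrors how results tables compare the
metric panel among top hits. **P-value selection** returns the top k
with all ties at the cutoff kept.

Simultaneous (parallel) testing of two markers uses
net sensitivity = s₁+s₂−s₁s₂ and net specificity = sp₁·sp₂, which assume
conditional independence given disease; `empirical_parallel_test`
computes the same quantities from the observed combined marker, and the
two agree to Monte-Carlo accuracy when independence holds.

## Regression, points and validation

Unconditional logistic models are fitted by maximum likelihood
(statsmodels Newton backend); quasi-separation (|coefficient| > 15) is
flagged and the fit marked non-converged. Conditional logistic models
for matched sets and 5-year age strata maximise the conditional
likelihood; strata without both a case and a control are dropped with a
warning. Estimates are validated against closed forms (discordant-pair
ratio for 1:1 matching) and brute-force enumeration of case subsets for
strata of size ≤ 6.

The stage-1 per-SNP adjusted odds ratios condition on the greedy matched
sets (each case takes the eligible control nearest in age, same sex and
available comorbidity flags, controls reusable — which is why a training
set can hold fewer controls than cases). The stage-2 final model for
point derivation is a plain logistic fit on the five dichotomous
predictors: a model conditioned on 5-year age strata cannot identify the
age>75 coefficient the point score needs.

**Points**: each coefficient is divided by the reference coefficient
(sex, the smallest dichotomous coefficient; if it is not positive the
smallest positive coefficient takes over with a warning) and rounded
**half-up to the nearest integer** — nearest-integer rounding, not
ceiling, is the convention consistent with the published point table
(0.91/0.37 = 2.46 → 2 points). Risk-group cuts default to the reference
fractions 6/18 and 11/18 of the maximum score, reproducing the canonical
0–6 / 7–11 / 12–18 partition at max score 18 and scaling sensibly when
the fitted point scale differs. Group odds ratios come from a logistic
fit with group indicators (low = reference); the trend P is a Wald test
on the group index as an ordinal score.

AUC is the Mann-Whitney statistic with ties counted ½; its 95% CI uses
the DeLong variance (validated against O(n²) pairwise computation).
LOOCV refits the model n times and scores each sample out-of-fold;
optimism = apparent − cross-validated AUC, and the corrected AUC equals
the cross-validated AUC by construction (asserted on every run).

## Synthetic-data generator

`simulate_study` emulates the two-stage retrospective design. A
population of 50 × (total cases) individuals receives covariates
(age ~ Normal(75, 6²) truncated at 65; 55% female; 35% with ≤ 6 years of
education; BMI ~ Normal(23.5, 3²); 20% ever-smokers — chosen to resemble
the reported cohort demographics, whose exact distributions are not
identifiable), independent HWE genotypes with MAF ~ U(0.05, 0.5)
(causal SNPs U(0.11, 0.5), the MAF range of the validated hits, keeping
true signals off the QC boundary), and a two-SNP APOE-like haplotype
locus (e2/e3/e4 frequencies 0.08/0.84/0.08; carrier odds ratios 3.5 for
one e4 copy, 17.7 for two). Disease follows a logistic model with
covariate log-odds 2.42 (age > 75), 0.37 (female), 2.11 (education ≤ 6)
and five causal SNPs with dominant odds ratios 6.4–11.6, the
discriminative strength reported for the training-set hits.

Two calibrations make the configuration parameters mean what their
labels say. The intercept is solved so the **population prevalence**
equals `baseline_prevalence` (default 0.05; anchoring the default to a
zero-risk reference individual would drive overall prevalence towards 1
once several strong common risk factors are present). Each causal
coefficient is solved (fixed-point iteration, jointly with the
intercept) so the **marginal** dominant-model odds ratio — the quantity
a case-control 2×2 table estimates — equals the configured value;
an uncalibrated conditional coefficient would realise a 1.4–2× smaller
marginal OR through non-collapsibility under this covariate
heterogeneity. With calibration, the 95% Wald CI of the crude dominant
OR covers the configured value at the nominal rate (96/100 seeds at
OR 9, stage-2 sizes).

Stage-1 cases are drawn from individuals meeting the training-set
restriction (18.5 < BMI < 27, never-smokers) and stage-1 controls are
drawn individually matched to cases (same sex, age ± 5 y), so the
matched-control covariate distribution mirrors the cases'. Matched
controls are thereby more strongly depleted of risk alleles, which
reproduces the reported pattern of crude DORs exceeding the
matched-conditional AORs. Stage 2 is sampled unrestricted from the
remainder. Missingness is injected per SNP: background rate 5e-4 plus a
2% fraction of poorly performing assays with 2–10% missingness — the
structure the 98% call-rate filter exists to catch (uniform missingness
at historical rates would make that filter remove ~7.5% of perfectly
good SNPs at n = 94).

The generator does **not** simulate linkage disequilibrium (SNPs are
independent given the haplotype locus), population structure,
genotyping batch effects, or genome-scale marker counts; passing tests
therefore demonstrate correctness of the statistical machinery and
calibration of the generator, not robustness to LD or stratification in
real data.

## Problem sizes and numerical choices

The test suite runs the pipeline at 300–2000 SNPs and the study's
reported sample sizes; the HWE oracle comparison is exhaustive to total
60 and sampled to 200; parameter-recovery coverage uses 200 seeds;
planted-signal recovery uses 12 seeds at 2000 SNPs. Logistic convergence
uses Newton iterations to score tolerance 1e-8 (conditional: 1e-10);
DeLong CIs are truncated to [0, 1]; metric comparisons round to 6
decimals; the greedy matcher breaks age ties by lowest sample id so runs
are deterministic, and every simulation is reproducible from its seed.

## Known limitations

- Full recovery of all five planted SNPs in the metric-rule top five is
  rare (typical overlap 3–4 of 5 at training-set sizes with 2000 nulls):
  the weakest planted marker's association signal at n = 94 is
  statistically indistinguishable from the extreme of ~2000 null
  markers, and single-metric-extreme null SNPs can capture 2–3 metric
  maxima in any pool. This is a property of the emulated design (printed
  training-set metrics are post-selection order statistics), not of the
  implementation.
- Exact reproduction of a given integer point vector from refitted
  coefficients is unstable whenever the reference (sex) coefficient is
  small relative to its standard error; the point *structure* (reference
  = 1 point; age/education dominating the genetic predictors) is what
  the pipeline tests assert.
- The per-SNP AUC model and the candidate-pool construction are
  reconstructions of under-specified steps; both are configurable.
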