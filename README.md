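# snpmetrics

Performance-metric SNP selection and point-based genetic risk modelling
for two-stage case-control studies.

## The problem

Genome-wide association studies traditionally rank markers by chi-square
P-value, which at stringent multiple-testing thresholds misses markers of
moderate effect and, without correction, admits chance extremes. An
alternative is to treat each SNP as a *diagnostic test*: code genotypes
under the dominant model (positive = carrier of at least one minor
allele), tabulate carriers against case status, and score each marker on
a panel of clinical-validity metrics,

- sensitivity = TP/(TP+FN), specificity = TN/(FP+TN)
- Youden index = sensitivity + specificity − 1
- PPV = TP/(TP+FP), NPV = TN/(FN+TN)
- diagnostic odds ratio DOR = (TP·TN)/(FP·FN)
- accuracy = (TP+TN)/N
- AUC of a covariate-adjusted logistic model containing the SNP,

then select the SNPs that attain the *largest number of metric maxima*
over the candidate pool. Two selected markers can be combined by parallel
testing (positive if either is positive), with

- net sensitivity = s₁ + s₂ − s₁·s₂ = 1 − (1−s₁)(1−s₂)
- net specificity = sp₁ · sp₂

under conditional independence given disease status — raising the low
sensitivity of a strong reference marker such as APOE e4 at a
quantifiable specificity cost. Finally, the winning SNP enters a
logistic model with dichotomous covariates (age > 75 y, female sex,
education ≤ 6 y, APOE e4 carrier, SNP carrier); each coefficient βᵢ is
converted to integer points = round-half-up(βᵢ / β_sex), where sex has
the smallest dichotomous coefficient, yielding a transparent additive
risk score that is stratified into low / moderate / high groups and
validated by leave-one-out cross-validation (optimism = apparent −
cross-validated AUC).

The package implements this pipeline end to end for late-onset
Alzheimer's-disease-style studies: PLINK text I/O, QC (call rates, MAF,
Hardy-Weinberg exact test in controls), vectorised per-SNP metrics,
both selection rules, matched-set conditional logistic regression,
DeLong AUC confidence intervals, LOOCV optimism, and a synthetic-data
generator that emulates the two-stage design (matched training set of
55 cases / 39 controls; validation set of 196 / 423) with known ground
truth, so every stage is testable without access to patient data.

## Worked example

`examples/05_risk_model.py` simulates a study, runs stage-1 selection and
stage-2 validation, and prints (abridged):

```
best overall SNP: snp00005
final model coefficients and points (reference: female = 1 point):
      age_gt75: coef +1.62 -> 18 points
        female: coef +0.09 -> 1 points
       edu_le6: coef +1.49 -> 16 points
       apoe_e4: coef +0.90 -> 10 points
   snp_carrier: coef +2.29 -> 25 points
total score range: 0-70

risk groups (score cuts 0-23 / 24-43 / 44-70):
        case  control
group0     9      222
group1    66      140
group2   121       61
adjusted odds ratios vs low-risk group:
           or  ci_low  ci_high
group1  11.63    5.62    24.08
group2  48.93   23.48   101.95
trend P: 1.26e-32

apparent AUC 0.859 (95% CI 0.830-0.889)
LOOCV AUC 0.839, optimism 0.0199, corrected 0.839
```

Each sample's score is the sum of the points of the risk conditions it
meets; the moderate- and high-risk groups carry ~12-fold and ~49-fold
higher disease odds than the low group, and the small optimism shows the
five-predictor model is not overfitting at this sample size. The other
examples cover simulation (`01`), QC and the HWE exact test (`02`), the
metric panel and parallel testing (`03`), and stage-1 selection (`04`).

A thin CLI wraps the same pipeline:

```bash
snpmetrics simulate --out data/ --seed 7
snpmetrics stage1 --data data/ --out run1/
snpmetrics stage2 --data data/ --stage1-out run1/ --out run2/
snpmetrics full-run --out run/ --seed 7
```

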