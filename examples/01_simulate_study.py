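"""Generate a synthetic two-stage case-control study with known truth.

Builds the default study: a matched, restricted training set (55 cases /
39 controls), an unrestricted validation set (196 / 423), 2000 autosomal
SNPs in HWE, five planted causal SNPs, an APOE-like two-SNP locus and
covariate effects on disease risk.
"""

import snpmetrics as sm

config = sm.SimulationConfig(seed=42, m_snps=2000)
study = sm.simulate_study(config)

g1, s1 = study.stage(1)
g2, s2 = study.stage(2)
print(f"population prevalence: {study.truth['population_disease_fraction']:.3f}")
print(f"stage 1: {int(s1.is_case.sum())} cases / {int((~s1.is_case).sum())} controls")
print(f"stage 2: {int(s2.is_case.sum())} cases / {int((~s2.is_case).sum())} controls")
print(f"SNPs (incl. the APOE pair): {study.genotypes.n_snps}")
print("planted causal SNPs and their marginal dominant odds ratios:")
for snp, orr in study.truth["causal_marginal_or"].items():
    print(f"  {snp}: OR {orr}")
print(f"APOE e4 carrier fraction, stage 2: {s2.data['apoe_e4'].mean():.3f}")

# The prevalence is the calibrated population disease risk; the planted
# odds ratios are what a dominant-model 2x2 table estimates in expectation.
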