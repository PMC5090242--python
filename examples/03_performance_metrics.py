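"""Diagnostic performance metrics of a SNP under the dominant model.

A marker is "positive" when the sample carries at least one minor allele.
From the resulting 2x2 table against case status the package computes the
performance-metric panel, and the parallel-testing (net) metrics of the
marker combined with a reference marker such as APOE e4.
"""

import numpy as np

import snpmetrics as sm

study = sm.simulate_study(sm.SimulationConfig(seed=3, m_snps=100))
geno, samples = study.stage(2)

snp = study.truth["causal_snp_ids"][2]  # the strongest planted SNP
codes = geno.matrix[:, geno.snp_index(snp)]
table = sm.dominant_table(codes, samples.is_case)
m = sm.performance_metrics(table)

print(f"{snp}: TP={table.tp} FP={table.fp} FN={table.fn} TN={table.tn}")
for name in ("sensitivity", "specificity", "youden", "ppv", "npv", "dor", "accuracy"):
    print(f"  {name:>12}: {getattr(m, name):.3f}")

# parallel testing with the APOE e4 carrier flag: positive if either is
apoe = samples.data["apoe_e4"].to_numpy(float)
apoe_m = sm.performance_metrics(sm.dominant_table(apoe.astype(int), samples.is_case))
print(f"\nAPOE e4 alone: sens {apoe_m.sensitivity:.2f}, spec {apoe_m.specificity:.2f}")
print("net sensitivity (formula):",
      f"{sm.net_sensitivity(apoe_m.sensitivity, m.sensitivity):.3f}")
print("net specificity (formula):",
      f"{sm.net_specificity(apoe_m.specificity, m.specificity):.3f}")
emp = sm.empirical_parallel_test(sm.carrier_vector(codes), apoe, samples.is_case)
print(f"empirical parallel test:    sens {emp.sensitivity:.3f}, spec {emp.specificity:.3f}")

# Net sensitivity always exceeds either single test; net specificity is
# the price paid: the product of the two specificities.
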