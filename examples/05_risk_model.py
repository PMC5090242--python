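"""Stage-2 validation and the point-based genetic risk model.

Re-checks HWE for the carried-forward SNPs, re-computes their metrics,
tests each in parallel with APOE e4, picks the best-overall SNP, fits the
five-predictor logistic model (age>75, sex, education<=6y, APOE e4, SNP
carrier), converts coefficients to integer points, stratifies risk groups
and reports apparent and LOOCV-corrected AUC.
"""

import warnings

import snpmetrics as sm

warnings.simplefilter("ignore")

study = sm.simulate_study(sm.SimulationConfig(seed=4, m_snps=500))
cfg = sm.RunConfig()
s1 = sm.run_stage1(*study.stage(1), cfg)
s2 = sm.run_stage2(*study.stage(2), s1.selection.selected, cfg)

print("carried-forward SNPs:", s1.selection.selected)
print("HWE re-check in stage-2 controls:")
print(s2.hwe_check.round(3))
print(f"\nbest overall SNP: {s2.best_snp}")
print("final model coefficients and points (reference: female = 1 point):")
for term, (coef, pts) in s2.point_model.entries.items():
    print(f"  {term:>12}: coef {coef:+.2f} -> {pts} points")
print(f"total score range: 0-{s2.point_model.max_score}")

cuts = " / ".join(f"{lo}-{hi}" for lo, hi in s2.point_model.group_cuts)
print(f"\nrisk groups (score cuts {cuts}):")
print(s2.grouping.counts)
print("adjusted odds ratios vs low-risk group:")
print(s2.grouping.aor[["or", "ci_low", "ci_high"]].round(2))
print(f"trend P: {s2.grouping.trend_p:.2e}")

print(f"\napparent AUC {s2.apparent_auc:.3f} (95% CI {s2.auc_ci[0]:.3f}-{s2.auc_ci[1]:.3f})")
print(f"LOOCV AUC {s2.cv.cv_auc:.3f}, optimism {s2.cv.optimism:.4f}, "
      f"corrected {s2.cv.corrected_auc:.3f}")

# Optimism = apparent - cross-validated AUC; the corrected AUC equals the
# cross-validated one by construction. A small optimism indicates the
# five-predictor model is not overfitting at this sample size.
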