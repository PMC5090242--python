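"""Synthetic two-stage case-control genotype studies with known truth.

The generator emulates a two-stage late-onset Alzheimer's disease study:
a small, restricted and matched training set (stage 1, 55 cases / 39
controls by default) genotyped genome-wide, and a larger validation set
(stage 2, 196 cases / 423 controls). Biallelic autosomal SNPs are drawn
under Hardy-Weinberg equilibrium; disease status is assigned by a logistic
model combining a handful of causal SNPs with dominant-model odds ratios,
an APOE-like two-SNP haplotype locus with strong carrier effects, and
covariate effects (age > 75, female sex, low education). Cases and
controls are then sampled retrospectively from a large population, which
reproduces case-control ascertainment without inverting the intercept.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import MISSING, GenotypeDataset, SampleTable, SnpInfo

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes_hwe",
    "simulate_apoe_locus",
    "simulate_study",
]

#: rs-style ids used for the two SNPs defining the APOE-like locus.
APOE_SNP_IDS = ("rs429358", "rs7412")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for a simulated two-stage study.

    Defaults mirror the study design being emulated: stage sizes 55/39 and
    196/423; five causal SNPs whose dominant odds ratios equal the
    discriminative strength (diagnostic odds ratios 6.4-11.6) reported for
    the five training-set hits; an APOE-like locus with haplotype
    frequencies ~0.08/0.84/0.08 (e2/e3/e4) and carrier odds ratios 3.5
    (one e4 copy) and 17.7 (two copies); covariate log-odds 2.42 / 0.37 /
    2.11 for age>75 / female / education<=6y.
    """

    seed: int = 0
    m_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    stage1_cases: int = 55
    stage1_controls: int = 39
    stage2_cases: int = 196
    stage2_controls: int = 423
    #: (snp index, dominant-model odds ratio) pairs
    causal_snps: tuple[tuple[int, float], ...] = (
        (0, 6.4),
        (1, 7.8),
        (2, 11.6),
        (3, 9.0),
        (4, 9.0),
    )
    #: causal SNPs draw their MAF here (validated hits had MAF 0.11-0.50),
    #: keeping them clear of the 0.05 QC boundary
    causal_maf_range: tuple[float, float] = (0.11, 0.5)
    #: haplotype frequencies (e2, e3, e4); must sum to 1
    apoe_hap_freqs: tuple[float, float, float] = (0.08, 0.84, 0.08)
    apoe_or_het: float = 3.5  # e3/e4 vs e3/e3
    apoe_or_hom: float = 17.7  # e4/e4 vs e3/e3
    #: log-odds per dichotomous covariate
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age_gt75": 2.42, "female": 0.37, "edu_le6": 2.11}
    )
    #: overall population disease prevalence the intercept is calibrated to
    baseline_prevalence: float = 0.05
    #: background per-genotype missing-call rate (well-behaved assays)
    missing_rate: float = 0.0005
    #: fraction of SNPs that are poorly performing assays, and the range
    #: their per-genotype missing rate is drawn from; these are the SNPs
    #: the call-rate QC filter exists to remove
    bad_assay_fraction: float = 0.02
    bad_assay_missing_range: tuple[float, float] = (0.02, 0.10)
    #: population size = multiplier x total cases requested
    population_multiplier: int = 50

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if abs(sum(self.apoe_hap_freqs) - 1.0) > 1e-9:
            raise ValueError("apoe_hap_freqs must sum to 1")
        if any(f < 0 for f in self.apoe_hap_freqs):
            raise ValueError("apoe_hap_freqs must be non-negative")
        for idx, orr in self.causal_snps:
            if orr <= 0:
                raise ValueError(f"odds ratio for SNP {idx} must be > 0")
            if not (0 <= idx < self.m_snps):
                raise ValueError(f"causal SNP index {idx} out of range")
        if self.apoe_or_het <= 0 or self.apoe_or_hom <= 0:
            raise ValueError("APOE odds ratios must be > 0")
        for n in (
            self.stage1_cases,
            self.stage1_controls,
            self.stage2_cases,
            self.stage2_controls,
        ):
            if n <= 0:
                raise ValueError("stage sizes must be positive")
        if not (0 < self.baseline_prevalence < 1):
            raise ValueError("baseline_prevalence must be in (0,1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0,1)")
        if not (0 <= self.bad_assay_fraction < 1):
            raise ValueError("bad_assay_fraction must be in [0,1)")


@dataclass
class SimulatedStudy:
    """A generated study: genotypes + samples + the truth that produced them."""

    genotypes: GenotypeDataset
    samples: SampleTable
    truth: dict

    def stage(self, which: int) -> tuple[GenotypeDataset, SampleTable]:
        """Genotypes and samples restricted to stage 1 or 2."""
        mask = (self.samples.data["stage"] == which).to_numpy()
        geno_mask = np.isin(
            self.genotypes.sample_ids,
            self.samples.data.loc[mask, "sample_id"].to_numpy(),
        )
        geno = self.genotypes.subset(sample_mask=geno_mask)
        return geno, self.samples.subset(mask).aligned_to(geno)


def simulate_genotypes_hwe(
    maf: float | np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw minor-allele dosage codes for ``n`` samples under HWE.

    Genotype probabilities are ``(1-maf)^2, 2 maf (1-maf), maf^2`` for codes
    0/1/2, i.e. two independent Bernoulli(maf) allele draws per sample.
    ``maf`` may be a scalar (returns shape ``(n,)``) or a vector of per-SNP
    frequencies (returns ``(n, m)``).
    """
    maf_arr = np.asarray(maf, dtype=float)
    if np.any((maf_arr <= 0) | (maf_arr >= 1)):
        raise ValueError("maf must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if maf_arr.ndim == 0:
        return rng.binomial(2, float(maf_arr), size=n).astype(np.int8)
    return rng.binomial(2, maf_arr[None, :], size=(n, maf_arr.size)).astype(np.int8)


def simulate_apoe_locus(
    freqs: Sequence[float], n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the two-SNP APOE-like locus for ``n`` samples.

    Each sample receives two haplotypes drawn i.i.d. from (e2, e3, e4) with
    the given frequencies. The e4 haplotype carries the minor allele of the
    rs429358-like SNP; the e2 haplotype carries the minor allele of the
    rs7412-like SNP; e3 is the reference haplotype. Returns
    ``(rs429358 codes, rs7412 codes, e4 carrier flags)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (3,) or np.any(freqs < 0) or abs(freqs.sum() - 1) > 1e-9:
        raise ValueError("freqs must be 3 non-negative values summing to 1")
    haps = rng.choice(3, size=(n, 2), p=freqs)  # 0=e2, 1=e3, 2=e4
    rs429358 = (haps == 2).sum(axis=1).astype(np.int8)  # e4 count
    rs7412 = (haps == 0).sum(axis=1).astype(np.int8)  # e2 count
    carrier = rs429358 >= 1
    return rs429358, rs7412, carrier


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw elderly-cohort covariates (age >= 65, education, BMI, smoking)."""
    # age ~ Normal(75, 6^2) truncated to >= 65 (resampling)
    age = rng.normal(75.0, 6.0, size=n)
    while True:
        bad = age < 65.0
        if not bad.any():
            break
        age[bad] = rng.normal(75.0, 6.0, size=int(bad.sum()))
    female = rng.random(n) < 0.55
    # education: ~35% with <= 6 years of schooling, rest 7-16
    low_edu = rng.random(n) < 0.35
    education = np.where(
        low_edu, rng.integers(0, 7, size=n), rng.integers(7, 17, size=n)
    ).astype(float)
    bmi = rng.normal(23.5, 3.0, size=n).clip(15.0, 40.0)
    smoking_ever = rng.random(n) < 0.20
    return pd.DataFrame(
        {
            "age": age,
            "sex": np.where(female, "F", "M"),
            "education": education,
            "bmi": bmi,
            "smoking": np.where(smoking_ever, "ever", "never"),
        }
    )


def _match_controls(
    rng: np.random.Generator,
    case_idx: np.ndarray,
    pool: np.ndarray,
    n_controls: int,
    age: np.ndarray,
    sex: np.ndarray,
) -> np.ndarray:
    """Sample controls individually matched (same sex, age +-5 y) to cases.

    One control is drawn per case for the first ``n_controls`` cases (in
    random order), without replacement; matching makes the control
    covariate distribution mirror the cases', as in a matched training
    set. When no exact match remains, the nearest-age same-sex candidate
    is taken, and failing that the nearest-age candidate.
    """
    if len(pool) < n_controls:
        raise ValueError(
            f"requested {n_controls} matched controls but only {len(pool)} "
            "eligible; increase population_multiplier"
        )
    order = rng.permutation(case_idx)[:n_controls]
    available = np.ones(len(pool), bool)
    chosen: list[int] = []
    for ci in order:
        cand = available & (sex[pool] == sex[ci]) & (np.abs(age[pool] - age[ci]) <= 5.0)
        if not cand.any():
            cand = available & (sex[pool] == sex[ci])
        if not cand.any():
            cand = available.copy()
        cand_idx = np.flatnonzero(cand)
        # random among exact matches; nearest-age when falling back
        if (np.abs(age[pool[cand_idx]] - age[ci]) <= 5.0).all():
            pick = rng.choice(cand_idx)
        else:
            pick = cand_idx[np.argmin(np.abs(age[pool[cand_idx]] - age[ci]))]
        available[pick] = False
        chosen.append(int(pool[pick]))
    return np.asarray(chosen)


def _sample_without_replacement(
    rng: np.random.Generator, pool: np.ndarray, k: int, label: str
) -> np.ndarray:
    if len(pool) < k:
        raise ValueError(
            f"requested {k} {label} but only {len(pool)} available; "
            "increase population_multiplier"
        )
    return rng.choice(pool, size=k, replace=False)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate a full two-stage case-control study from ``config``.

    A population of ``population_multiplier x (stage1_cases + stage2_cases)``
    individuals is generated; disease is assigned by the logistic model and
    the configured numbers of cases and controls are sampled without
    replacement per stage. Stage-1 samples are drawn only from individuals
    meeting the training-set restriction (18.5 < BMI < 27, never-smokers),
    mirroring the restricted, matched design; stage 2 is unrestricted.
    Genotype missingness is injected at ``missing_rate`` after sampling.
    """
    rng = np.random.default_rng(config.seed)
    n_pop = config.population_multiplier * (config.stage1_cases + config.stage2_cases)

    cov = _simulate_covariates(n_pop, rng)
    mafs = rng.uniform(*config.maf_range, size=config.m_snps)
    for idx, _orr in config.causal_snps:
        mafs[idx] = rng.uniform(*config.causal_maf_range)
    geno = simulate_genotypes_hwe(mafs, n_pop, rng)
    rs429358, rs7412, e4_carrier = simulate_apoe_locus(
        config.apoe_hap_freqs, n_pop, rng
    )

    eff = dict(config.covariate_effects)
    eta = np.zeros(n_pop)
    eta += eff.get("age_gt75", 0.0) * (cov["age"].to_numpy() > 75)
    eta += eff.get("female", 0.0) * (cov["sex"].to_numpy() == "F")
    eta += eff.get("edu_le6", 0.0) * (cov["education"].to_numpy() <= 6)
    het_e4 = rs429358 == 1
    hom_e4 = rs429358 == 2
    eta += math.log(config.apoe_or_het) * het_e4
    eta += math.log(config.apoe_or_hom) * hom_e4
    # Calibrate (a) the intercept so the POPULATION prevalence equals the
    # configured value and (b) each causal-SNP coefficient so its MARGINAL
    # dominant-model odds ratio in the population equals the configured
    # odds ratio. The configured value is the quantity a case-control 2x2
    # table estimates; an uncalibrated logistic coefficient would realise a
    # smaller marginal odds ratio because of covariate risk heterogeneity
    # (non-collapsibility of the odds ratio).
    from scipy import optimize, special

    target_prev = config.baseline_prevalence
    carriers = {idx: geno[:, idx] >= 1 for idx, _ in config.causal_snps}
    coefs = {idx: math.log(orr) for idx, orr in config.causal_snps}
    b0 = 0.0
    for _ in range(25):
        eta_full = eta + sum(c * carriers[i] for i, c in coefs.items())
        b0 = optimize.brentq(
            lambda b: float(special.expit(b + eta_full).mean() - target_prev),
            -40.0, 40.0, xtol=1e-12,
        )
        max_step = 0.0
        for (idx, orr) in config.causal_snps:
            p = special.expit(b0 + eta_full)
            z = carriers[idx]
            p1, p0 = p[z].mean(), p[~z].mean()
            implied = (p1 / (1 - p1)) / (p0 / (1 - p0))
            step = math.log(orr) - math.log(implied)
            coefs[idx] += step
            eta_full = eta_full + step * z
            max_step = max(max_step, abs(step))
        if max_step < 1e-10:
            break
    p_disease = special.expit(b0 + eta_full)
    disease = rng.random(n_pop) < p_disease

    restricted = (
        (cov["bmi"].to_numpy() > 18.5)
        & (cov["bmi"].to_numpy() < 27.0)
        & (cov["smoking"].to_numpy() == "never")
    )
    all_idx = np.arange(n_pop)
    s1_cases = _sample_without_replacement(
        rng, all_idx[disease & restricted], config.stage1_cases, "stage-1 cases"
    )
    s1_controls = _match_controls(
        rng,
        case_idx=s1_cases,
        pool=all_idx[~disease & restricted],
        n_controls=config.stage1_controls,
        age=cov["age"].to_numpy(),
        sex=cov["sex"].to_numpy(),
    )
    used = np.zeros(n_pop, bool)
    used[s1_cases] = used[s1_controls] = True
    s2_cases = _sample_without_replacement(
        rng, all_idx[disease & ~used], config.stage2_cases, "stage-2 cases"
    )
    s2_controls = _sample_without_replacement(
        rng, all_idx[~disease & ~used], config.stage2_controls, "stage-2 controls"
    )

    chosen = np.concatenate([s1_cases, s1_controls, s2_cases, s2_controls])
    stage = np.concatenate(
        [
            np.ones(len(s1_cases) + len(s1_controls), int),
            np.full(len(s2_cases) + len(s2_controls), 2),
        ]
    )
    pheno = np.concatenate(
        [
            np.repeat("case", len(s1_cases)),
            np.repeat("control", len(s1_controls)),
            np.repeat("case", len(s2_cases)),
            np.repeat("control", len(s2_controls)),
        ]
    )

    width = len(str(len(chosen)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(len(chosen))]

    matrix = np.concatenate(
        [geno[chosen], rs429358[chosen, None], rs7412[chosen, None]], axis=1
    ).astype(np.int8)
    # per-SNP missingness: low background plus a minority of bad assays
    m_total = matrix.shape[1]
    snp_miss_rate = np.full(m_total, config.missing_rate)
    bad = rng.random(m_total) < config.bad_assay_fraction
    snp_miss_rate[bad] = rng.uniform(*config.bad_assay_missing_range, size=int(bad.sum()))
    if snp_miss_rate.max() > 0:
        miss = rng.random(matrix.shape) < snp_miss_rate[None, :]
        matrix[miss] = MISSING

    snps: list[SnpInfo] = []
    for j in range(config.m_snps):
        chrom = str(j % 22 + 1)
        snps.append(SnpInfo(f"snp{j + 1:05d}", chrom, 1000 + 100 * j, "A", "G"))
    # APOE-like SNPs live on chromosome 19
    snps.append(SnpInfo(APOE_SNP_IDS[0], "19", 45411941, "C", "T"))
    snps.append(SnpInfo(APOE_SNP_IDS[1], "19", 45412079, "T", "C"))

    genotypes = GenotypeDataset(sample_ids=sample_ids, snps=snps, matrix=matrix)
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "phenotype": pheno,
                "age": cov["age"].to_numpy()[chosen],
                "sex": cov["sex"].to_numpy()[chosen],
                "education": cov["education"].to_numpy()[chosen],
                "bmi": cov["bmi"].to_numpy()[chosen],
                "smoking": cov["smoking"].to_numpy()[chosen],
                "apoe_e4": e4_carrier[chosen].astype(int),
                "stage": stage,
            }
        )
    )
    truth = {
        "config": config,
        "mafs": mafs,
        "causal_snp_ids": [f"snp{idx + 1:05d}" for idx, _ in config.causal_snps],
        #: target marginal dominant odds ratios (what a 2x2 table estimates)
        "causal_marginal_or": {
            f"snp{idx + 1:05d}": orr for idx, orr in config.causal_snps
        },
        #: realized conditional logistic coefficients after calibration
        "causal_log_or": {f"snp{idx + 1:05d}": coefs[idx] for idx, _ in config.causal_snps},
        "population_disease_fraction": float(disease.mean()),
    }
    return SimulatedStudy(genotypes=genotypes, samples=samples, truth=truth)
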