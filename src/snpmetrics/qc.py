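"""SNP and sample quality control for case-control genotype data.

Filters follow the usual microarray pruning order: non-autosomal SNPs out
first, then samples with genotyping success rate < 90%, then SNPs with
call rate < 98%, MAF < 0.05 (control subset by default) and Hardy-Weinberg
exact-test P < 1e-4 among controls. The HWE test is the exact conditional
test (two-sided by summing heterozygote configurations no more probable
than the observed one), the same test PLINK applies with ``--hwe``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset, SampleTable

__all__ = [
    "QCThresholds",
    "HWECounts",
    "QCReport",
    "hwe_exact_test",
    "hwe_chisq_test",
    "snp_call_rate",
    "sample_call_rate",
    "minor_allele_freq",
    "apply_qc",
    "qq_data",
]

AUTOSOMES = {str(c) for c in range(1, 23)}


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds for the QC filters."""

    min_sample_rate: float = 0.90  # per-sample genotyping success rate
    min_snp_rate: float = 0.98  # per-SNP call rate
    min_maf: float = 0.05
    hwe_alpha: float = 1e-4  # exact-test P in controls
    autosomes_only: bool = True
    #: MAF over all samples by default: the exclusion criteria name controls
    #: explicitly only for the HWE test, and a control-only MAF in a small
    #: matched training set is dominated by sampling noise
    maf_controls_only: bool = False

    def __post_init__(self) -> None:
        for r in (self.min_sample_rate, self.min_snp_rate):
            if not (0 < r <= 1):
                raise ValueError("call-rate thresholds must be in (0, 1]")
        if not (0 <= self.min_maf < 1):
            raise ValueError("min_maf must be in [0, 1)")
        if not (0 < self.hwe_alpha < 1):
            raise ValueError("hwe_alpha must be in (0, 1)")


@dataclass(frozen=True)
class HWECounts:
    """Genotype counts (major-hom, het, minor-hom), typically among controls."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one genotyped sample required")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


@dataclass
class QCReport:
    """Per-filter removal tallies plus per-SNP MAF and HWE P-values."""

    n_samples_in: int
    n_snps_in: int
    removed_snps_non_autosomal: list[str] = field(default_factory=list)
    removed_samples_low_rate: list[str] = field(default_factory=list)
    removed_snps_low_rate: list[str] = field(default_factory=list)
    removed_snps_low_maf: list[str] = field(default_factory=list)
    removed_snps_hwe: list[str] = field(default_factory=list)
    snp_maf: dict[str, float] = field(default_factory=dict)
    snp_hwe_p: dict[str, float] = field(default_factory=dict)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.removed_samples_low_rate)

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - (
            len(self.removed_snps_non_autosomal)
            + len(self.removed_snps_low_rate)
            + len(self.removed_snps_low_maf)
            + len(self.removed_snps_hwe)
        )

    def summary(self) -> dict:
        return {
            "samples_in": self.n_samples_in,
            "samples_removed_low_rate": len(self.removed_samples_low_rate),
            "samples_out": self.n_samples_out,
            "snps_in": self.n_snps_in,
            "snps_removed_non_autosomal": len(self.removed_snps_non_autosomal),
            "snps_removed_low_call_rate": len(self.removed_snps_low_rate),
            "snps_removed_low_maf": len(self.removed_snps_low_maf),
            "snps_removed_hwe": len(self.removed_snps_hwe),
            "snps_out": self.n_snps_out,
        }


def hwe_exact_test(counts: HWECounts) -> float:
    """Two-sided Hardy-Weinberg exact test P-value.

    Conditions on the observed allele counts and sums, over all possible
    heterozygote counts with the correct parity, the probabilities of every
    configuration no more probable than the observed one. Probabilities are
    computed by the stable ratio recurrence over heterozygote counts.
    """
    n = counts.total
    n_het = counts.n_Aa
    # rare-allele count (orientation does not matter; test is symmetric)
    n_rare = 2 * min(counts.n_AA, counts.n_aa) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: a single possible configuration

    # possible het counts share the parity of n_rare
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = list(range(het_min, het_max + 1, 2))

    # unnormalized probabilities by recurrence:
    # P(h+2)/P(h) = 4*hom_rare(h)*hom_common(h) / ((h+2)*(h+1))
    probs = {}
    h_mid = hets[len(hets) // 2]
    probs[h_mid] = 1.0
    for h in range(h_mid, het_max, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for h in range(h_mid, het_min, -2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))

    total = sum(probs.values())
    p_obs = probs[n_het] / total
    # sum configurations no more probable than the observed (small slack
    # keeps equal-probability ties included despite float noise)
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_chisq_test(counts: HWECounts) -> float:
    """One-df chi-square HWE test (provided for comparison only)."""
    from scipy import stats

    n = counts.total
    p = (2 * counts.n_AA + counts.n_Aa) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([counts.n_AA, counts.n_Aa, counts.n_aa])
    if np.any(exp == 0):
        return 1.0
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(stat, df=1))


def _hwe_counts_from_codes(codes: np.ndarray) -> HWECounts | None:
    ok = codes != MISSING
    if not ok.any():
        return None
    c = codes[ok]
    return HWECounts(int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum()))


def snp_call_rate(dataset: GenotypeDataset, snp_id: str) -> float:
    """Fraction of samples with a non-missing call at the SNP."""
    j = dataset.snp_index(snp_id)
    return float((dataset.matrix[:, j] != MISSING).mean())


def sample_call_rate(dataset: GenotypeDataset, sample_id: str) -> float:
    """Fraction of SNPs with a non-missing call for the sample."""
    i = dataset.sample_index(sample_id)
    return float((dataset.matrix[i, :] != MISSING).mean())


def minor_allele_freq(
    dataset: GenotypeDataset, snp_id: str, subset: np.ndarray | None = None
) -> tuple[float, bool]:
    """Minor allele frequency at a SNP, optionally within a sample subset.

    Returns ``(maf, flipped)`` where ``flipped`` records that the coded
    allele had frequency > 0.5 in the subset so the orientation was flipped
    for reporting. All-missing subsets raise ``ValueError``.
    """
    j = dataset.snp_index(snp_id)
    codes = dataset.matrix[:, j]
    if subset is not None:
        codes = codes[np.asarray(subset, bool)]
    ok = codes != MISSING
    if not ok.any():
        raise ValueError(f"SNP {snp_id}: all calls missing in subset")
    freq = float(codes[ok].sum()) / (2.0 * int(ok.sum()))
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


def apply_qc(
    dataset: GenotypeDataset,
    samples: SampleTable,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeDataset, SampleTable, QCReport]:
    """Apply the QC filters in fixed order and tally removals.

    Order: (1) non-autosomal SNPs, (2) low-rate samples, (3) low-call-rate
    SNPs, (4) low-MAF SNPs (control subset by default), (5) control-HWE
    failures. An empty result at any step is reported, not raised.
    """
    samples = samples.aligned_to(dataset)
    report = QCReport(n_samples_in=dataset.n_samples, n_snps_in=dataset.n_snps)

    # (1) autosomes
    if thresholds.autosomes_only:
        keep = np.array([s.chrom in AUTOSOMES for s in dataset.snps])
        report.removed_snps_non_autosomal = [
            s.snp_id for s, k in zip(dataset.snps, keep) if not k
        ]
        dataset = dataset.subset(snp_mask=keep)

    miss = dataset.matrix == MISSING

    # (2) samples by genotyping success rate
    if dataset.n_snps > 0:
        rate = 1.0 - miss.mean(axis=1)
        keep_s = rate >= thresholds.min_sample_rate
    else:
        keep_s = np.ones(dataset.n_samples, bool)
    report.removed_samples_low_rate = [
        sid for sid, k in zip(dataset.sample_ids, keep_s) if not k
    ]
    dataset = dataset.subset(sample_mask=keep_s)
    keep_rows = samples.data["sample_id"].isin(dataset.sample_ids).to_numpy()
    samples = samples.subset(keep_rows).aligned_to(dataset)
    miss = dataset.matrix == MISSING

    # (3) SNPs by call rate
    if dataset.n_samples > 0:
        rate = 1.0 - miss.mean(axis=0)
        keep_v = rate >= thresholds.min_snp_rate
    else:
        keep_v = np.ones(dataset.n_snps, bool)
    report.removed_snps_low_rate = [
        s.snp_id for s, k in zip(dataset.snps, keep_v) if not k
    ]
    dataset = dataset.subset(snp_mask=keep_v)

    # (4) MAF and (5) HWE, on the control subset
    controls = ~samples.is_case
    maf_subset = controls if thresholds.maf_controls_only else np.ones(len(samples), bool)
    keep_maf = np.ones(dataset.n_snps, bool)
    for j, s in enumerate(dataset.snps):
        codes = dataset.matrix[:, j][maf_subset]
        ok = codes != MISSING
        if not ok.any():
            keep_maf[j] = False
            report.snp_maf[s.snp_id] = float("nan")
            continue
        freq = float(codes[ok].sum()) / (2.0 * int(ok.sum()))
        maf = min(freq, 1 - freq)
        report.snp_maf[s.snp_id] = maf
        if maf < thresholds.min_maf:
            keep_maf[j] = False
    report.removed_snps_low_maf = [
        s.snp_id for s, k in zip(dataset.snps, keep_maf) if not k
    ]
    dataset = dataset.subset(snp_mask=keep_maf)

    keep_hwe = np.ones(dataset.n_snps, bool)
    for j, s in enumerate(dataset.snps):
        counts = _hwe_counts_from_codes(dataset.matrix[:, j][controls])
        if counts is None:
            p = float("nan")
            keep_hwe[j] = False
        else:
            p = hwe_exact_test(counts)
            if p < thresholds.hwe_alpha:
                keep_hwe[j] = False
        report.snp_hwe_p[s.snp_id] = p
    report.removed_snps_hwe = [
        s.snp_id for s, k in zip(dataset.snps, keep_hwe) if not k
    ]
    dataset = dataset.subset(snp_mask=keep_hwe)

    return dataset, samples, report


def qq_data(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 P quantiles for a QQ plot.

    ``expected_i = -log10((i - 0.5) / m)`` paired with the i-th smallest
    observed P-value, i = 1..m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no P-values supplied")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P-values must lie in (0, 1]")
    m = p.size
    order = np.sort(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(order)
    return pd.DataFrame({"expected": expected, "observed": observed})
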