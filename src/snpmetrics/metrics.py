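"""Dominant-model diagnostic performance metrics and SNP selection rules.

Each SNP is treated as a binary diagnostic test under the dominant genetic
model: a sample is "positive" when it carries at least one copy of the
minor (variant) allele. From the resulting 2x2 table against case status
the ten performance metrics are computed: sensitivity, specificity, Youden
index, PPV, NPV, diagnostic odds ratio, accuracy, net sensitivity and net
specificity of parallel testing with a reference marker (APOE e4 in the
motivating study), and AUC of a covariate-adjusted logistic model.

Two selection rules are provided: the metric-count rule (rank SNPs by how
many metrics they maximise over the candidate pool) and traditional
P-value ranking with ties kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeDataset

__all__ = [
    "DominantTable",
    "MetricSet",
    "AssocStats",
    "SelectionResult",
    "dominant_table",
    "carrier_vector",
    "performance_metrics",
    "net_sensitivity",
    "net_specificity",
    "empirical_parallel_test",
    "snp_chisq",
    "bonferroni_threshold",
    "select_by_metric_counts",
    "select_by_pvalue",
    "TABLE_METRICS",
    "ALL_METRICS",
]

#: metrics computable from the 2x2 table alone (all higher-is-better)
TABLE_METRICS = (
    "sensitivity",
    "specificity",
    "youden",
    "ppv",
    "npv",
    "dor",
    "accuracy",
)
#: the full ten-metric panel used by the metric-count selection rule
ALL_METRICS = TABLE_METRICS + ("net_sensitivity", "net_specificity", "auc")


@dataclass(frozen=True)
class DominantTable:
    """2x2 carrier/non-carrier vs case/control contingency table.

    TP = carrier cases, FP = carrier controls, FN = non-carrier cases,
    TN = non-carrier controls. ``orientation`` records which allele defines
    "carrier" (the minor allele throughout this package).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    orientation: str = "minor-allele carrier"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class MetricSet:
    """The performance-metric panel for one marker (or marker pair).

    ``dor`` is ``inf`` when FP*FN = 0 with TP*TN > 0 and ``nan`` (undefined)
    when both products vanish; other undefined ratios (empty margin) are
    ``nan``. ``net_sensitivity``/``net_specificity`` and ``auc`` are filled
    in by the pipeline where a reference marker / adjusted model applies.
    """

    sensitivity: float
    specificity: float
    youden: float
    ppv: float
    npv: float
    dor: float
    accuracy: float
    net_sensitivity: float | None = None
    net_specificity: float | None = None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in TABLE_METRICS}
        d["net_sensitivity"] = self.net_sensitivity
        d["net_specificity"] = self.net_specificity
        d["auc"] = self.auc
        return d


@dataclass(frozen=True)
class AssocStats:
    """Association test result for one SNP."""

    chi2: float
    p_value: float
    variant: str  # "allelic" or "dominant"


@dataclass
class SelectionResult:
    """Ranked candidates under the metric-count rule.

    ``table`` holds one row per candidate with its metrics, the count of
    metrics in which it attains the pool maximum, and the rank; ``selected``
    is the top-k slice of the ranking.
    """

    table: pd.DataFrame
    selected: list[str]
    k: int
    metrics_used: tuple[str, ...]


def carrier_vector(codes: np.ndarray) -> np.ndarray:
    """Carrier status under the dominant model; missing codes become NaN."""
    codes = np.asarray(codes)
    out = np.where(codes == MISSING, np.nan, (codes >= 1).astype(float))
    return out


def dominant_table(
    codes: np.ndarray, is_case: np.ndarray, orientation: str = "minor-allele carrier"
) -> DominantTable:
    """Build the dominant-model 2x2 table for one SNP.

    ``codes`` are minor-allele dosages (missing excluded pairwise);
    ``is_case`` is a boolean phenotype vector of the same length.
    """
    codes = np.asarray(codes)
    is_case = np.asarray(is_case, bool)
    if codes.shape != is_case.shape:
        raise ValueError("codes and phenotype differ in length")
    ok = codes != MISSING
    if not (is_case & ok).any() or not (~is_case & ok).any():
        raise ValueError("need at least one genotyped case and control")
    carrier = codes >= 1
    tp = int((carrier & is_case & ok).sum())
    fp = int((carrier & ~is_case & ok).sum())
    fn = int((~carrier & is_case & ok).sum())
    tn = int((~carrier & ~is_case & ok).sum())
    return DominantTable(tp, fp, fn, tn, orientation)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def performance_metrics(table: DominantTable) -> MetricSet:
    """Compute the seven table-derived metrics from a 2x2 table.

    sensitivity = TP/(TP+FN); specificity = TN/(FP+TN);
    Youden = sensitivity + specificity - 1; PPV = TP/(TP+FP);
    NPV = TN/(FN+TN); DOR = (TP/FP)/(FN/TN) = TP*TN/(FP*FN);
    accuracy = (TP+TN)/total.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, fp + tn)
    if fp * fn == 0:
        dor = float("inf") if tp * tn > 0 else float("nan")
    else:
        dor = (tp * tn) / (fp * fn)
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, fn + tn),
        dor=dor,
        accuracy=_ratio(tp + tn, table.total),
    )


def _check_unit(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def net_sensitivity(sens_a: float, sens_b: float) -> float:
    """Net sensitivity of two tests in parallel (positive if either is).

    ``sA + sB - sA*sB``, i.e. ``1 - (1-sA)(1-sB)``; assumes the tests are
    conditionally independent given disease status.
    """
    _check_unit(sens_a, "sens_a")
    _check_unit(sens_b, "sens_b")
    return sens_a + sens_b - sens_a * sens_b


def net_specificity(spec_a: float, spec_b: float) -> float:
    """Net specificity of two tests in parallel: the product ``spA * spB``."""
    _check_unit(spec_a, "spec_a")
    _check_unit(spec_b, "spec_b")
    return spec_a * spec_b


def empirical_parallel_test(
    carrier_a: np.ndarray, carrier_b: np.ndarray, is_case: np.ndarray
) -> MetricSet:
    """Metrics of the combined marker "positive if either marker positive".

    Inputs are binary (or NaN-for-missing) marker vectors; samples with a
    missing value in either marker are excluded.
    """
    a = np.asarray(carrier_a, float)
    b = np.asarray(carrier_b, float)
    y = np.asarray(is_case, bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("marker and phenotype vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    combined = ((a[ok] > 0) | (b[ok] > 0)).astype(int)
    return performance_metrics(dominant_table(combined, y[ok], orientation="either-positive"))


def snp_chisq(
    codes: np.ndarray, is_case: np.ndarray, variant: str = "allelic"
) -> AssocStats:
    """1-df Pearson chi-square association test for one SNP.

    ``variant="allelic"`` tests the 2x2 allele-count table (each sample
    contributes two alleles); ``variant="dominant"`` tests the carrier
    table. A zero margin yields ``p = nan``.
    """
    codes = np.asarray(codes)
    is_case = np.asarray(is_case, bool)
    ok = codes != MISSING
    codes, is_case = codes[ok], is_case[ok]
    if variant == "allelic":
        minor_case = int(codes[is_case].sum())
        minor_ctrl = int(codes[~is_case].sum())
        tot_case = 2 * int(is_case.sum())
        tot_ctrl = 2 * int((~is_case).sum())
        obs = np.array(
            [[minor_case, tot_case - minor_case], [minor_ctrl, tot_ctrl - minor_ctrl]]
        )
    elif variant == "dominant":
        t = dominant_table(codes, is_case)
        obs = np.array([[t.tp, t.fn], [t.fp, t.tn]])
    else:
        raise ValueError(f"unknown test variant {variant!r}")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return AssocStats(float("nan"), float("nan"), variant)
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return AssocStats(float(chi2), float(p), variant)


def chisq_allelic_vectorized(
    matrix: np.ndarray, is_case: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Allelic chi-square statistics and P-values for every SNP column."""
    is_case = np.asarray(is_case, bool)
    ok = matrix != MISSING
    codes = np.where(ok, matrix, 0)
    a_case = (codes * is_case[:, None]).sum(axis=0).astype(float)
    a_ctrl = (codes * (~is_case)[:, None]).sum(axis=0).astype(float)
    n_case = 2.0 * (ok & is_case[:, None]).sum(axis=0)
    n_ctrl = 2.0 * (ok & (~is_case)[:, None]).sum(axis=0)
    b_case = n_case - a_case
    b_ctrl = n_ctrl - a_ctrl
    n = n_case + n_ctrl
    col_a = a_case + a_ctrl
    col_b = b_case + b_ctrl
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (a_case * b_ctrl - b_case * a_ctrl) ** 2 * n
        den = n_case * n_ctrl * col_a * col_b
        chi2 = np.where(den > 0, num / den, np.nan)
    p = np.where(np.isnan(chi2), np.nan, stats.chi2.sf(chi2, df=1))
    return chi2, p


def bonferroni_threshold(alpha: float, m_snps: int) -> float:
    """Bonferroni-corrected per-test significance threshold ``alpha / m``."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    return alpha / m_snps


def select_by_metric_counts(
    metric_table: pd.DataFrame,
    k: int,
    metrics: Sequence[str] = ALL_METRICS,
    p_values: pd.Series | None = None,
) -> SelectionResult:
    """Rank SNPs by the number of metrics in which they attain the maximum.

    For each metric (all higher-is-better), every SNP tied at the pool
    maximum scores one count; values are rounded to 6 decimals first so
    float noise cannot manufacture a unique maximum. SNPs with an undefined
    value sit out that metric's comparison. Ties in the count are broken by
    mean metric rank, then AUC (descending), then P-value (ascending), then
    snp_id.
    """
    if len(metric_table) < k:
        raise ValueError(f"need >= {k} candidates, got {len(metric_table)}")
    metrics = tuple(metrics)
    missing_cols = [m for m in metrics if m not in metric_table.columns]
    if missing_cols:
        raise ValueError(f"metric columns absent from table: {missing_cols}")

    vals = metric_table[list(metrics)].astype(float).round(6)
    counts = pd.Series(0, index=metric_table.index, dtype=int)
    ranks = pd.DataFrame(index=metric_table.index)
    for m in metrics:
        col = vals[m]
        if col.notna().any():
            mx = col.max()  # NaN-aware; inf allowed (DOR)
            counts += (col == mx).fillna(False).astype(int)
        ranks[m] = col.rank(ascending=False, method="average")
    mean_rank = ranks.mean(axis=1, skipna=True)

    out = metric_table.copy()
    out["metric_count"] = counts
    out["mean_metric_rank"] = mean_rank
    auc = vals["auc"] if "auc" in vals.columns else pd.Series(np.nan, index=out.index)
    pv = (
        p_values.reindex(out.index)
        if p_values is not None
        else out.get("p_value", pd.Series(np.nan, index=out.index))
    )
    order = pd.DataFrame(
        {
            "_count": -counts,
            "_mean_rank": mean_rank,
            "_auc": -auc.fillna(-np.inf),
            "_p": pv.astype(float).fillna(np.inf),
            "_id": out.index.astype(str),
        }
    ).sort_values(["_count", "_mean_rank", "_auc", "_p", "_id"])
    ranked = out.loc[order.index]
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return SelectionResult(
        table=ranked,
        selected=list(ranked.index[:k].astype(str)),
        k=k,
        metrics_used=metrics,
    )


def select_by_pvalue(p_values: pd.Series, k: int) -> list[str]:
    """Top-k SNP ids by ascending P-value, keeping every tie at the cutoff.

    If several SNPs share the k-th smallest P-value the result exceeds k,
    mirroring the "top six because of ties" situation.
    """
    p = p_values.astype(float).dropna().sort_values(kind="mergesort")
    if k <= 0:
        return []
    if len(p) <= k:
        return list(p.index.astype(str))
    cutoff = p.iloc[k - 1]
    return list(p[p <= cutoff].index.astype(str))
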