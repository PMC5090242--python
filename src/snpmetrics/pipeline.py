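"""Two-stage study orchestration: QC, selection, validation, risk model.

Stage 1 (training set): QC, per-SNP dominant-model metrics and allelic
chi-square P-values for every SNP, metric-count and P-value selection,
QQ/Manhattan data, conditional-logistic adjusted odds ratios on the
matched sets for the top SNPs. Stage 2 (validation set): HWE re-check of
the carried-forward SNPs, metric re-computation, simultaneous (parallel)
testing of each with the APOE-e4-like reference marker, choice of the
best-overall SNP, the final five-predictor logistic model, the integer
point score, risk groups with adjusted odds ratios and a trend test, and
apparent / LOOCV-corrected AUC.

Metric-count ranking (and the per-SNP adjusted AUCs and net
sensitivity/specificity it needs) operates on a candidate pool of the
top-N SNPs by association P-value; see :func:`_candidate_pool` for why a
genome-wide pool degenerates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    MISSING,
    GenotypeDataset,
    SampleTable,
    write_covariates,
    write_ped_map,
    write_results_tsv,
)
from .matching import MatchCriteria, MatchResult, restrict_and_match
from .metrics import (
    ALL_METRICS,
    SelectionResult,
    bonferroni_threshold,
    carrier_vector,
    chisq_allelic_vectorized,
    dominant_table,
    empirical_parallel_test,
    net_sensitivity,
    net_specificity,
    performance_metrics,
    select_by_metric_counts,
    select_by_pvalue,
)
from .qc import HWECounts, QCReport, QCThresholds, apply_qc, hwe_exact_test, qq_data
from .riskmodel import (
    DEFAULT_GROUP_CUTS,
    CVResult,
    LogisticFit,
    PointModel,
    RiskGrouping,
    assign_groups,
    auc_delong,
    derive_points,
    fit_conditional_logistic,
    fit_logistic,
    group_aor_and_trend,
    loocv_optimism,
    total_score,
)
from .synthetic import APOE_SNP_IDS, SimulationConfig, SimulatedStudy, simulate_study

__all__ = [
    "RunConfig",
    "Stage1Result",
    "Stage2Result",
    "snp_metric_table",
    "run_stage1",
    "run_stage2",
    "full_run",
]


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run parameters."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    match: MatchCriteria = field(default_factory=MatchCriteria)
    k_select: int = 5
    prescreen_top_n: int = 50
    aor_top_n: int = 10
    alpha: float = 0.05
    #: explicit risk-group score cuts; None scales the reference cuts
    #: (low <= 6/18, moderate <= 11/18 of the maximum) to the realized
    #: score range, which reproduces 0-6 / 7-11 / 12-18 at max score 18
    group_cuts: tuple[tuple[int, int], ...] | None = None
    reference_term: str = "female"
    #: marker ids excluded from genome-wide candidacy (genotyped separately)
    excluded_snp_ids: tuple[str, ...] = APOE_SNP_IDS

    def __post_init__(self) -> None:
        if self.k_select < 1:
            raise ValueError("k_select must be >= 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_kwargs = raw.get("simulate", {})
        if "causal_snps" in sim_kwargs:
            sim_kwargs["causal_snps"] = tuple(
                (int(i), float(o)) for i, o in sim_kwargs["causal_snps"]
            )
        for key in ("maf_range", "apoe_hap_freqs"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim_kwargs) - known
        if bad:
            raise ValueError(f"unknown [simulate] keys: {sorted(bad)}")
        sel = raw.get("selection", {})
        model = raw.get("model", {})
        qc_kwargs = raw.get("qc", {})
        bad = set(qc_kwargs) - {f.name for f in dataclasses.fields(QCThresholds)}
        if bad:
            raise ValueError(f"unknown [qc] keys: {sorted(bad)}")
        cuts = model.get("group_cuts")
        return cls(
            simulation=SimulationConfig(**sim_kwargs),
            qc=QCThresholds(**qc_kwargs),
            k_select=int(sel.get("k", 5)),
            prescreen_top_n=int(sel.get("prescreen_top_n", 50)),
            aor_top_n=int(sel.get("aor_top_n", 10)),
            group_cuts=tuple(tuple(c) for c in cuts) if cuts else None,
            reference_term=model.get("reference_term", "female"),
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, simulation=dataclasses.replace(self.simulation, seed=seed)
        )


@dataclass
class Stage1Result:
    qc_report: QCReport
    metrics: pd.DataFrame  # per-SNP metrics + chi2 + p (pool rows carry auc/net)
    selection: SelectionResult
    selected_by_pvalue: list[str]
    match_result: MatchResult
    aor_table: pd.DataFrame
    qq: pd.DataFrame
    manhattan: pd.DataFrame
    bonferroni: float
    apoe_sens: float
    apoe_spec: float


@dataclass
class Stage2Result:
    hwe_check: pd.DataFrame
    metrics: pd.DataFrame
    parallel: pd.DataFrame
    best_snp: str
    final_fit: LogisticFit
    point_model: PointModel
    scores: pd.Series
    grouping: RiskGrouping
    apparent_auc: float
    auc_ci: tuple[float, float]
    cv: CVResult
    n_excluded_missing: int


def _dichotomize(samples: SampleTable) -> pd.DataFrame:
    """The study's standard dichotomous covariates per sample."""
    df = samples.data
    out = pd.DataFrame(index=df.index)
    out["age_gt75"] = (df["age"] > 75).astype(float)
    out["female"] = (df["sex"] == "F").astype(float)
    if "education" in df:
        out["edu_le6"] = (df["education"] <= 6).astype(float)
    if "apoe_e4" in df:
        out["apoe_e4"] = df["apoe_e4"].astype(float)
    return out


def snp_metric_table(
    genotypes: GenotypeDataset, samples: SampleTable
) -> pd.DataFrame:
    """Vectorized dominant-model table metrics for every SNP.

    Returns a DataFrame indexed by snp_id with TP/FP/FN/TN and the seven
    table metrics, missing genotypes excluded pairwise.
    """
    samples = samples.aligned_to(genotypes)
    is_case = samples.is_case
    ok = genotypes.matrix != MISSING
    carrier = (genotypes.matrix >= 1) & ok
    noncarrier = (genotypes.matrix == 0) & ok
    tp = (carrier & is_case[:, None]).sum(axis=0).astype(float)
    fp = (carrier & ~is_case[:, None]).sum(axis=0).astype(float)
    fn = (noncarrier & is_case[:, None]).sum(axis=0).astype(float)
    tn = (noncarrier & ~is_case[:, None]).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(fp + tn > 0, tn / (fp + tn), np.nan)
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        npv = np.where(fn + tn > 0, tn / (fn + tn), np.nan)
        acc = (tp + tn) / (tp + fp + fn + tn)
        dor = np.where(
            fp * fn > 0, tp * tn / (fp * fn), np.where(tp * tn > 0, np.inf, np.nan)
        )
    return pd.DataFrame(
        {
            "tp": tp.astype(int),
            "fp": fp.astype(int),
            "fn": fn.astype(int),
            "tn": tn.astype(int),
            "sensitivity": sens,
            "specificity": spec,
            "youden": sens + spec - 1.0,
            "ppv": ppv,
            "npv": npv,
            "dor": dor,
            "accuracy": acc,
        },
        index=pd.Index(genotypes.snp_ids, name="snp_id"),
    )


def _apoe_marker_metrics(samples: SampleTable) -> tuple[float, float]:
    """Empirical sensitivity/specificity of the APOE-e4 carrier flag."""
    carrier = samples.data["apoe_e4"].to_numpy(float)
    t = dominant_table(carrier.astype(int), samples.is_case, orientation="e4 carrier")
    m = performance_metrics(t)
    return m.sensitivity, m.specificity


def _snp_adjusted_auc(
    genotypes: GenotypeDataset,
    samples: SampleTable,
    snp_id: str,
) -> float:
    """AUC of a logistic model with the SNP carrier plus forced covariates.

    Covariates: age (years), female, education (years), APOE e4 carrier —
    the panel the per-SNP AUC column is defined over.
    """
    j = genotypes.snp_index(snp_id)
    codes = genotypes.matrix[:, j]
    ok = codes != MISSING
    df = samples.data.loc[ok]
    X = pd.DataFrame(
        {
            "snp": (codes[ok] >= 1).astype(float),
            "age": df["age"].to_numpy(float),
            "female": (df["sex"] == "F").astype(float).to_numpy(),
            "education": df["education"].to_numpy(float),
            "apoe_e4": df["apoe_e4"].to_numpy(float),
        }
    )
    y = samples.is_case[ok].astype(int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_logistic(X, y)
    except Exception:
        return float("nan")
    auc, _, _ = auc_delong(fit.predict_proba(X), y)
    return auc


def _candidate_pool(p: pd.Series, top_n: int) -> pd.Index:
    """Candidate pool for metric-count ranking: top-N SNPs by P-value.

    Comparing metric maxima over every genome-wide SNP degenerates — with
    thousands of null markers, chance tables (e.g. zero control carriers
    giving PPV = 1 and an infinite DOR) monopolise the per-metric maxima —
    so the metric panel is compared among association-supported candidates,
    the way a results table lists metrics for the top hits. Ties at the
    cutoff P-value are all kept.
    """
    p = p.dropna().sort_values(kind="mergesort")
    if len(p) <= top_n:
        return pd.Index(sorted(p.index))
    cutoff = p.iloc[top_n - 1]
    return pd.Index(sorted(p[p <= cutoff].index))


def run_stage1(
    genotypes: GenotypeDataset,
    samples: SampleTable,
    config: RunConfig = RunConfig(),
) -> Stage1Result:
    """QC, per-SNP metrics, selection and matched-set AORs on the training set."""
    geno, samp, qc_report = apply_qc(genotypes, samples, config.qc)

    candidate_mask = ~np.isin(geno.snp_ids, config.excluded_snp_ids)
    cand = geno.subset(snp_mask=candidate_mask)

    table = snp_metric_table(cand, samp)
    chi2, p = chisq_allelic_vectorized(cand.matrix, samp.aligned_to(cand).is_case)
    table["chi2"] = chi2
    table["p_value"] = p
    pseries = pd.Series(p, index=table.index)

    apoe_sens, apoe_spec = _apoe_marker_metrics(samp)

    pool = _candidate_pool(pseries, config.prescreen_top_n)
    table["net_sensitivity"] = np.nan
    table["net_specificity"] = np.nan
    table["auc"] = np.nan
    table.loc[pool, "net_sensitivity"] = [
        net_sensitivity(apoe_sens, s) if np.isfinite(s) else np.nan
        for s in table.loc[pool, "sensitivity"]
    ]
    table.loc[pool, "net_specificity"] = [
        net_specificity(apoe_spec, s) if np.isfinite(s) else np.nan
        for s in table.loc[pool, "specificity"]
    ]
    table.loc[pool, "auc"] = [
        _snp_adjusted_auc(cand, samp, sid) for sid in pool
    ]

    selection = select_by_metric_counts(
        table.loc[pool], config.k_select, metrics=ALL_METRICS,
        p_values=pseries.loc[pool],
    )
    by_pvalue = select_by_pvalue(pseries, config.k_select)

    # matched-set conditional-logistic AORs for the leading SNPs
    match_result = restrict_and_match(samp, config.match)
    analysis = match_result.analysis_table(samp)
    top_ids = list(
        dict.fromkeys(list(selection.table.index[: config.aor_top_n]) + by_pvalue)
    )
    aor_rows = []
    id_to_col = {sid: cand.snp_index(sid) for sid in cand.snp_ids}
    sample_row = {sid: i for i, sid in enumerate(cand.sample_ids)}
    for sid in top_ids:
        codes = cand.matrix[
            [sample_row[s] for s in analysis["sample_id"]], id_to_col[sid]
        ]
        okv = codes != MISSING
        X = pd.DataFrame({"carrier": (codes[okv] >= 1).astype(float)})
        y = (analysis.loc[okv, "phenotype"] == "case").astype(int).to_numpy()
        strata = analysis.loc[okv, "matched_set_id"].to_numpy()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_conditional_logistic(strata, X, y)
            orr = fit.odds_ratios().loc["carrier"]
            aor_rows.append(
                {
                    "snp_id": sid,
                    "aor": orr["or"],
                    "ci_low": orr["ci_low"],
                    "ci_high": orr["ci_high"],
                    "converged": fit.converged,
                }
            )
        except Exception as exc:  # uninformative strata etc.
            aor_rows.append(
                {"snp_id": sid, "aor": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "converged": False}
            )
    aor_table = pd.DataFrame(aor_rows).set_index("snp_id") if aor_rows else pd.DataFrame()

    finite_p = pseries.dropna()
    qq = qq_data(finite_p.to_numpy())
    man = pd.DataFrame(
        {
            "snp_id": table.index,
            "chrom": [s.chrom for s in cand.snps],
            "pos": [s.pos for s in cand.snps],
            "p_value": p,
        }
    )
    return Stage1Result(
        qc_report=qc_report,
        metrics=table,
        selection=selection,
        selected_by_pvalue=by_pvalue,
        match_result=match_result,
        aor_table=aor_table,
        qq=qq,
        manhattan=man,
        bonferroni=bonferroni_threshold(config.alpha, max(1, len(table))),
        apoe_sens=apoe_sens,
        apoe_spec=apoe_spec,
    )


def _scaled_group_cuts(max_score: int) -> tuple[tuple[int, int], ...]:
    """Low/moderate/high cuts proportional to the reference 6/18 and 11/18.

    Reproduces the canonical 0-6 / 7-11 / 12-18 partition when the maximum
    score is 18 and keeps three non-empty score bands otherwise.
    """
    if max_score < 3:
        return ((0, max_score),)
    c1 = max(0, round(max_score * 6 / 18))
    c2 = min(max_score - 1, max(c1 + 1, round(max_score * 11 / 18)))
    return ((0, c1), (c1 + 1, c2), (c2 + 1, max_score))


def run_stage2(
    genotypes: GenotypeDataset,
    samples: SampleTable,
    selected_snps: list[str],
    config: RunConfig = RunConfig(),
) -> Stage2Result:
    """Validate the carried-forward SNPs and build the point-based model."""
    samples = samples.aligned_to(genotypes)
    is_case = samples.is_case
    controls = ~is_case

    # HWE re-check among controls for the carried-forward SNPs
    hwe_rows = []
    for sid in selected_snps:
        codes = genotypes.matrix[:, genotypes.snp_index(sid)][controls]
        okc = codes != MISSING
        c = codes[okc]
        counts = HWECounts(int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum()))
        freq = c.sum() / (2.0 * len(c))
        hwe_rows.append(
            {"snp_id": sid, "maf": min(freq, 1 - freq), "hwe_p": hwe_exact_test(counts)}
        )
    hwe_check = pd.DataFrame(hwe_rows).set_index("snp_id")

    sub_mask = np.isin(genotypes.snp_ids, selected_snps)
    sub = genotypes.subset(snp_mask=sub_mask)
    table = snp_metric_table(sub, samples).loc[selected_snps]
    _, p = chisq_allelic_vectorized(sub.matrix, samples.aligned_to(sub).is_case)
    table["p_value"] = pd.Series(p, index=sub.snp_ids).loc[selected_snps].to_numpy()

    apoe_sens, apoe_spec = _apoe_marker_metrics(samples)
    apoe_carrier = samples.data["apoe_e4"].to_numpy(float)

    par_rows = []
    for sid in selected_snps:
        codes = genotypes.matrix[:, genotypes.snp_index(sid)]
        emp = empirical_parallel_test(carrier_vector(codes), apoe_carrier, is_case)
        m = table.loc[sid]
        par_rows.append(
            {
                "snp_id": sid,
                "net_sensitivity": net_sensitivity(apoe_sens, m["sensitivity"]),
                "net_specificity": net_specificity(apoe_spec, m["specificity"]),
                "empirical_net_sensitivity": emp.sensitivity,
                "empirical_net_specificity": emp.specificity,
            }
        )
    parallel = pd.DataFrame(par_rows).set_index("snp_id")
    table["net_sensitivity"] = parallel["net_sensitivity"]
    table["net_specificity"] = parallel["net_specificity"]
    table["auc"] = [_snp_adjusted_auc(genotypes, samples, sid) for sid in selected_snps]

    # best overall SNP: highest metric count, ties broken by AUC then id;
    # monomorphic (carrier-invariant) SNPs fall back to the next-ranked
    sel = select_by_metric_counts(
        table, k=1, metrics=ALL_METRICS, p_values=table["p_value"]
    )
    ranked = sel.table.sort_values(
        ["metric_count", "auc", "p_value"], ascending=[False, False, True],
        kind="mergesort",
    )
    best_snp = None
    for sid in ranked.index:
        codes = genotypes.matrix[:, genotypes.snp_index(sid)]
        okv = codes != MISSING
        carr = codes[okv] >= 1
        if carr.min() == carr.max():
            warnings.warn(f"SNP {sid} is carrier-monomorphic in stage 2; skipping",
                          stacklevel=2)
            continue
        best_snp = sid
        break
    if best_snp is None:
        raise ValueError("all candidate SNPs are monomorphic in stage 2")

    # final model: five dichotomous predictors
    codes = genotypes.matrix[:, genotypes.snp_index(best_snp)]
    okv = codes != MISSING
    ind = _dichotomize(samples).loc[okv].reset_index(drop=True)
    ind["snp_carrier"] = (codes[okv] >= 1).astype(float)
    y = is_case[okv].astype(int)
    final_fit = fit_logistic(ind, y)

    ref = config.reference_term
    coefs = final_fit.coef_dict()
    if coefs.get(ref, -1.0) <= 0:
        positive = {
            t: c for t, c in coefs.items() if t != "intercept" and c > 0
        }
        if not positive:
            raise ValueError("no positive coefficient available as point reference")
        ref = min(positive, key=positive.get)
        warnings.warn(
            f"reference term {config.reference_term!r} has non-positive "
            f"coefficient; using smallest positive coefficient {ref!r}",
            stacklevel=2,
        )
    point_model = derive_points(final_fit, ref, group_cuts=DEFAULT_GROUP_CUTS)
    cuts = (
        config.group_cuts
        if config.group_cuts is not None
        else _scaled_group_cuts(point_model.max_score)
    )
    point_model.group_cuts = cuts
    scores = total_score(ind, point_model)
    groups = assign_groups(scores, cuts)
    grouping = group_aor_and_trend(groups, y, cuts=cuts)
    apparent, ci, _ = auc_delong(scores.to_numpy(), y)
    cv = loocv_optimism(ind, y)
    return Stage2Result(
        hwe_check=hwe_check,
        metrics=table,
        parallel=parallel,
        best_snp=best_snp,
        final_fit=final_fit,
        point_model=point_model,
        scores=scores,
        grouping=grouping,
        apparent_auc=apparent,
        auc_ci=ci,
        cv=cv,
        n_excluded_missing=int((~okv).sum()),
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)


def full_run(
    config: RunConfig,
    out_dir: str | Path | None = None,
    study: SimulatedStudy | None = None,
) -> tuple[Stage1Result, Stage2Result]:
    """Simulate (unless a study is supplied), run both stages, write reports."""
    if study is None:
        study = simulate_study(config.simulation)
    geno1, samp1 = study.stage(1)
    geno2, samp2 = study.stage(2)
    s1 = run_stage1(geno1, samp1, config)
    s2 = run_stage2(geno2, samp2, s1.selection.selected, config)
    if out_dir is not None:
        write_reports(config, study, s1, s2, Path(out_dir))
    return s1, s2


def write_reports(
    config: RunConfig,
    study: SimulatedStudy,
    s1: Stage1Result,
    s2: Stage2Result,
    out: Path,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_results_tsv(s1.metrics.reset_index(), out / "metrics.tsv")
    write_results_tsv(
        pd.DataFrame([s1.qc_report.summary()]), out / "qc_report.tsv"
    )
    write_results_tsv(s1.qq, out / "qq.tsv")
    write_results_tsv(s1.manhattan, out / "manhattan.tsv")
    selection = {
        "metric_rule": s1.selection.selected,
        "pvalue_rule": s1.selected_by_pvalue,
        "bonferroni_threshold": s1.bonferroni,
        "best_snp_stage2": s2.best_snp,
    }
    (out / "selection.json").write_text(json.dumps(selection, indent=2, default=_json_default))
    model_report = {
        "terms": s2.final_fit.terms,
        "coefficients": dict(zip(s2.final_fit.terms, s2.final_fit.coef)),
        "points": s2.point_model.points,
        "reference_term": s2.point_model.reference_term,
        "max_score": s2.point_model.max_score,
        "apparent_auc": s2.apparent_auc,
        "auc_ci": list(s2.auc_ci),
        "cv_auc": s2.cv.cv_auc,
        "optimism": s2.cv.optimism,
        "corrected_auc": s2.cv.corrected_auc,
        "trend_p": s2.grouping.trend_p,
    }
    (out / "model_report.json").write_text(
        json.dumps(model_report, indent=2, default=_json_default)
    )
    write_results_tsv(
        pd.DataFrame({"score": s2.scores}), out / "scores.tsv"
    )
    write_results_tsv(s2.grouping.counts.reset_index(), out / "groups.tsv")
    cfg_json = json.dumps(dataclasses.asdict(config), default=_json_default, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.simulation.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_samples": study.genotypes.n_samples,
        "n_snps": study.genotypes.n_snps,
        "qc": s1.qc_report.summary(),
        "selected": s1.selection.selected,
        "best_snp": s2.best_snp,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
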