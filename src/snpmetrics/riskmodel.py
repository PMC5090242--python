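"""Logistic modelling, point-based risk scores and internal validation.

Covers the modelling half of the pipeline: (conditional) logistic
regression fits, conversion of logistic coefficients into an integer
point score (each coefficient divided by the smallest dichotomous
coefficient — sex in the motivating study — and rounded half-up to the
nearest integer), risk-group stratification with adjusted odds ratios and
a trend test, AUC with DeLong confidence intervals, and leave-one-out
cross-validated optimism correction of the AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticFit",
    "PointModel",
    "RiskGrouping",
    "CVResult",
    "fit_logistic",
    "fit_conditional_logistic",
    "derive_points",
    "total_score",
    "assign_groups",
    "group_aor_and_trend",
    "auc_delong",
    "loocv_optimism",
    "DEFAULT_GROUP_CUTS",
]

#: (low, high) inclusive score ranges for the low/moderate/high risk groups
DEFAULT_GROUP_CUTS = ((0, 6), (7, 11), (12, 18))

SEPARATION_BOUND = 15.0  # |coef| beyond this flags quasi-separation


@dataclass
class LogisticFit:
    """A fitted (conditional) logistic model."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    separation: bool = False

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coef))

    def odds_ratios(self, z: float = 1.959963984540054) -> pd.DataFrame:
        """Odds ratios with Wald 95% CIs, one row per term."""
        lo = np.exp(self.coef - z * self.se)
        hi = np.exp(self.coef + z * self.se)
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "or": np.exp(self.coef),
             "ci_low": lo, "ci_high": hi},
            index=self.terms,
        )

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xm = _design_matrix(X, self.terms)
        eta = Xm @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class PointModel:
    """Integer point values derived from logistic coefficients.

    ``entries`` maps predictor name -> (coefficient, points); the reference
    predictor (smallest dichotomous coefficient, sex in the motivating
    model) defines one point.
    """

    entries: dict[str, tuple[float, int]]
    reference_term: str
    group_cuts: tuple[tuple[int, int], ...] = DEFAULT_GROUP_CUTS

    @property
    def points(self) -> dict[str, int]:
        return {k: v[1] for k, v in self.entries.items()}

    @property
    def max_score(self) -> int:
        return sum(p for _, p in self.entries.values())


@dataclass
class RiskGrouping:
    """Risk-group composition, group AORs vs the low group, and trend test."""

    cuts: tuple[tuple[int, int], ...]
    counts: pd.DataFrame  # groups x (case, control)
    aor: pd.DataFrame  # OR + CI per non-reference group
    trend_p: float


@dataclass
class CVResult:
    """Apparent vs cross-validated AUC and the optimism correction.

    By construction ``corrected = apparent - optimism = cross-validated``;
    both are stored and their consistency asserted.
    """

    apparent_auc: float
    cv_auc: float
    optimism: float
    corrected_auc: float
    n_folds: int
    n_failed_folds: int = 0

    def __post_init__(self) -> None:
        assert abs(self.corrected_auc - self.cv_auc) < 1e-12, (
            "corrected AUC must equal cross-validated AUC"
        )


def _design_matrix(X, terms: list[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if terms is not None:
            cols = [t for t in terms if t != "intercept"]
            Xm = X[cols].to_numpy(float)
            if "intercept" in terms:
                icol = terms.index("intercept")
                Xm = np.insert(Xm, icol, 1.0, axis=1)
            return Xm
        return X.to_numpy(float)
    return np.asarray(X, float)


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int] | np.ndarray,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression.

    ``X`` is the predictor matrix (a DataFrame keeps term names); an
    intercept is prepended unless ``add_intercept=False``. Quasi-separation
    (any |coefficient| > 15) is flagged and the fit marked non-converged.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(float)
    else:
        Xm = np.atleast_2d(np.asarray(X, float))
        if Xm.shape[0] != len(y):
            Xm = Xm.T
        names = [f"x{i}" for i in range(Xm.shape[1])]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(y)), Xm])
        names = ["intercept"] + names

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xm).fit(disp=0, method="newton", maxiter=max_iter, tol=tol)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            # fall back to a damped BFGS fit so coefficients are still reported
            res = sm.Logit(y, Xm).fit(disp=0, method="bfgs", maxiter=max_iter * 5)
            converged = False
    coef = np.asarray(res.params, float)
    se = np.asarray(res.bse, float)
    separation = bool(np.any(np.abs(coef) > SEPARATION_BOUND))
    if separation:
        warnings.warn("possible separation: |coefficient| > 15", stacklevel=2)
        converged = False
    return LogisticFit(
        terms=names,
        coef=coef,
        se=se,
        loglik=float(res.llf),
        converged=converged,
        separation=separation,
    )


def fit_conditional_logistic(
    strata: Sequence, X: pd.DataFrame | np.ndarray, y: Sequence[int]
) -> LogisticFit:
    """Conditional logistic regression for matched / stratified designs.

    Maximises the conditional likelihood given the number of cases per
    stratum. Strata contributing no information (all cases or all
    controls) are dropped with a warning.
    """
    from statsmodels.discrete.conditional_models import ConditionalLogit

    y = np.asarray(y, float)
    strata = np.asarray(strata)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(float)
    else:
        Xm = np.atleast_2d(np.asarray(X, float))
        if Xm.shape[0] != len(y):
            Xm = Xm.T
        names = [f"x{i}" for i in range(Xm.shape[1])]

    keep = np.ones(len(y), bool)
    for s in np.unique(strata):
        m = strata == s
        if y[m].min() == y[m].max():
            keep &= ~m
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} samples in uninformative strata", stacklevel=2
        )
    if not keep.any():
        raise ValueError("no informative strata (each needs a case and a control)")
    y, Xm, strata = y[keep], Xm[keep], strata[keep]

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ConditionalLogit(y, Xm, groups=strata)
        try:
            res = model.fit(disp=0, method="newton", maxiter=500, tol=1e-10)
            retvals = getattr(res, "mle_retvals", None)
            converged = bool(retvals.get("converged", True)) if retvals else True
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            converged = False
    coef = np.asarray(res.params, float)
    se = np.asarray(res.bse, float)
    separation = bool(np.any(np.abs(coef) > SEPARATION_BOUND))
    if separation:
        warnings.warn("possible separation: |coefficient| > 15", stacklevel=2)
        converged = False
    return LogisticFit(
        terms=names,
        coef=coef,
        se=se,
        loglik=float(res.llf),
        converged=converged,
        separation=separation,
    )


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


def derive_points(
    coefficients: "LogisticFit | dict[str, float]",
    reference_term: str,
    group_cuts: tuple[tuple[int, int], ...] = DEFAULT_GROUP_CUTS,
) -> PointModel:
    """Convert logistic coefficients to integer points.

    Each coefficient is divided by the reference coefficient (the smallest
    dichotomous coefficient in the model, e.g. sex) and rounded half-up to
    the nearest integer; the reference predictor itself earns 1 point.
    """
    coefs = (
        coefficients.coef_dict() if isinstance(coefficients, LogisticFit) else dict(coefficients)
    )
    coefs.pop("intercept", None)
    if reference_term not in coefs:
        raise KeyError(f"reference term {reference_term!r} not in model")
    ref = coefs[reference_term]
    if ref <= 0:
        raise ValueError(
            f"reference coefficient must be positive (got {ref}); "
            "re-specify the reference predictor"
        )
    entries = {
        name: (c, round_half_up(c / ref)) for name, c in coefs.items()
    }
    return PointModel(entries=entries, reference_term=reference_term, group_cuts=group_cuts)


def total_score(
    indicators: pd.DataFrame, point_model: PointModel
) -> pd.Series:
    """Sum of earned points per sample.

    ``indicators`` has one 0/1 column per predictor in the point model; a
    missing (NaN) predictor flags the sample with a NaN score.
    """
    missing_cols = [t for t in point_model.entries if t not in indicators.columns]
    if missing_cols:
        raise KeyError(f"predictors absent from indicator table: {missing_cols}")
    score = pd.Series(0.0, index=indicators.index)
    for name, (_c, pts) in point_model.entries.items():
        score = score + indicators[name].astype(float) * pts
    return score


def assign_groups(
    scores: pd.Series | np.ndarray,
    cuts: tuple[tuple[int, int], ...] = DEFAULT_GROUP_CUTS,
) -> np.ndarray:
    """Map scores to group indices 0..len(cuts)-1; out-of-range/NaN -> -1."""
    s = np.asarray(scores, float)
    out = np.full(s.shape, -1, int)
    for g, (lo, hi) in enumerate(cuts):
        out[(s >= lo) & (s <= hi)] = g
    return out


def group_aor_and_trend(
    groups: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    cuts: tuple[tuple[int, int], ...] = DEFAULT_GROUP_CUTS,
) -> RiskGrouping:
    """Odds ratios of each risk group vs the lowest, plus a trend test.

    AORs come from a logistic fit with group indicator terms (low group as
    reference, optional covariate adjustment); the trend P-value is the
    Wald test on the group index entered as an ordinal 0/1/2... score.
    """
    groups = np.asarray(groups, int)
    y = np.asarray(y, int)
    ok = groups >= 0
    groups, y = groups[ok], y[ok]
    present = np.unique(groups)
    if len(present) < 2:
        raise ValueError("need at least two populated risk groups")

    counts = pd.DataFrame(
        {
            "case": [int(((groups == g) & (y == 1)).sum()) for g in present],
            "control": [int(((groups == g) & (y == 0)).sum()) for g in present],
        },
        index=[f"group{g}" for g in present],
    )

    X = pd.DataFrame(index=np.arange(len(y)))
    for g in present[1:]:
        X[f"group{g}"] = (groups == g).astype(float)
    if covariates is not None:
        cov = covariates.loc[np.asarray(ok, bool)].reset_index(drop=True)
        for c in cov.columns:
            X[c] = cov[c].astype(float).to_numpy()
    fit = fit_logistic(X, y)
    aor = fit.odds_ratios().loc[[f"group{g}" for g in present[1:]]]

    Xt = pd.DataFrame({"ordinal": groups.astype(float)})
    if covariates is not None:
        for c in covariates.columns:
            Xt[c] = covariates.loc[np.asarray(ok, bool), c].astype(float).to_numpy()
    tfit = fit_logistic(Xt, y)
    i = tfit.terms.index("ordinal")
    z = tfit.coef[i] / tfit.se[i]
    trend_p = float(2 * stats.norm.sf(abs(z)))
    return RiskGrouping(cuts=cuts, counts=counts, aor=aor, trend_p=trend_p)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_delong(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """AUC with DeLong 95% confidence interval.

    AUC is the Mann-Whitney probability that a random case outscores a
    random control, ties counted one half. Returns
    ``(auc, (ci_low, ci_high), se)``; the CI is truncated to [0, 1].
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = 1.959963984540054
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return float(auc), ci, float(se)


def loocv_optimism(
    X: pd.DataFrame,
    y: np.ndarray,
    fit_fn: Callable[[pd.DataFrame, np.ndarray], LogisticFit] | None = None,
) -> CVResult:
    """Leave-one-out cross-validated AUC and the optimism correction.

    Each sample is scored by the model refit without it; the
    cross-validated AUC is computed from the pooled out-of-fold scores.
    optimism = apparent - cross-validated; corrected = apparent - optimism.
    Folds whose refit fails are excluded and counted.
    """
    y = np.asarray(y, int)
    fit_fn = fit_fn or (lambda Xs, ys: fit_logistic(Xs, ys))
    full = fit_fn(X, y)
    apparent, _, _ = auc_delong(full.predict_proba(X), y)

    n = len(y)
    oof = np.full(n, np.nan)
    failed = 0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        try:
            f = fit_fn(X.iloc[mask], y[mask])
            oof[i] = f.predict_proba(X.iloc[[i]])[0]
        except Exception:
            failed += 1
    ok = ~np.isnan(oof)
    cv_auc, _, _ = auc_delong(oof[ok], y[ok])
    optimism = apparent - cv_auc
    return CVResult(
        apparent_auc=float(apparent),
        cv_auc=float(cv_auc),
        optimism=float(optimism),
        corrected_auc=float(apparent - optimism),
        n_folds=n,
        n_failed_folds=failed,
    )
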