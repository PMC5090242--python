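"""Restriction and case-control matching for the training set.

Emulates the restricted, matched design of the stage-1 training set:
samples are first restricted (BMI strictly inside a window, never-smokers
only), then each case is greedily matched to the eligible control closest
in age (within a tolerance, exact match on sex and any configured
comorbidity flags). A control may serve several cases, which is why the
training set can have fewer controls than cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SampleTable

__all__ = ["MatchCriteria", "MatchResult", "restrict_and_match"]


@dataclass(frozen=True)
class MatchCriteria:
    """Restriction and matching rules for the training set."""

    age_tolerance: float = 5.0
    exact_vars: tuple[str, ...] = ("sex",)
    #: comorbidity flags matched exactly when the column is present
    comorbidity_vars: tuple[str, ...] = (
        "hypertension",
        "diabetes",
        "hypercholesterolemia",
        "head_injury",
    )
    bmi_window: tuple[float, float] = (18.5, 27.0)  # exclusive bounds
    never_smokers_only: bool = True
    allow_control_reuse: bool = True

    def __post_init__(self) -> None:
        if self.age_tolerance < 0:
            raise ValueError("age_tolerance must be >= 0")
        lo, hi = self.bmi_window
        if lo >= hi:
            raise ValueError("bmi_window lower bound must be < upper bound")


@dataclass
class MatchResult:
    """Matched pairs plus restriction/matching bookkeeping."""

    pairs: pd.DataFrame  # columns: matched_set_id, case_id, control_id, age_diff
    n_cases_in: int
    n_controls_in: int
    n_excluded_restriction: int
    dropped_cases: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_distinct_controls(self) -> int:
        return self.pairs["control_id"].nunique()

    def analysis_table(self, samples: SampleTable) -> pd.DataFrame:
        """Long-format rows for conditional logistic analysis.

        One case row and one control row per matched set; a reused control
        appears once per set it serves, with the set id in
        ``matched_set_id``.
        """
        df = samples.data.set_index("sample_id")
        rows = []
        for rec in self.pairs.itertuples():
            for sid in (rec.case_id, rec.control_id):
                row = df.loc[sid].to_dict()
                row["sample_id"] = sid
                row["matched_set_id"] = rec.matched_set_id
                rows.append(row)
        return pd.DataFrame(rows)


def restrict_and_match(
    samples: SampleTable, criteria: MatchCriteria = MatchCriteria()
) -> MatchResult:
    """Apply the restriction window, then greedily match cases to controls.

    Cases are processed in stable sorted order of sample_id; each picks the
    eligible control minimising |age difference| (ties broken by lowest
    control sample_id). Controls are reusable when
    ``criteria.allow_control_reuse``. Cases with no eligible control are
    dropped and reported. Raises if no pair can be formed.
    """
    df = samples.data.copy()
    n_in = len(df)

    eligible = np.ones(n_in, bool)
    if "bmi" in df.columns:
        lo, hi = criteria.bmi_window
        eligible &= (df["bmi"].to_numpy(float) > lo) & (df["bmi"].to_numpy(float) < hi)
    if criteria.never_smokers_only and "smoking" in df.columns:
        eligible &= (df["smoking"] == "never").to_numpy()
    restricted = df.loc[eligible].reset_index(drop=True)

    exact_vars = list(criteria.exact_vars) + [
        v for v in criteria.comorbidity_vars if v in restricted.columns
    ]
    skipped = [v for v in criteria.comorbidity_vars if v not in restricted.columns]
    if skipped:
        warnings.warn(
            f"comorbidity matching variables absent, skipped: {skipped}", stacklevel=2
        )

    cases = restricted[restricted["phenotype"] == "case"].sort_values("sample_id")
    controls = restricted[restricted["phenotype"] == "control"].sort_values("sample_id")

    pairs = []
    used_controls: set[str] = set()
    dropped: list[str] = []
    for set_id, case in enumerate(cases.itertuples(), start=1):
        cand = controls
        for v in exact_vars:
            cand = cand[cand[v] == getattr(case, v)]
        age_diff = (cand["age"] - case.age).abs()
        cand = cand.assign(_age_diff=age_diff)
        cand = cand[cand["_age_diff"] <= criteria.age_tolerance]
        if not criteria.allow_control_reuse:
            cand = cand[~cand["sample_id"].isin(used_controls)]
        if cand.empty:
            dropped.append(case.sample_id)
            continue
        best = cand.sort_values(["_age_diff", "sample_id"]).iloc[0]
        used_controls.add(best["sample_id"])
        pairs.append(
            {
                "matched_set_id": set_id,
                "case_id": case.sample_id,
                "control_id": best["sample_id"],
                "age_diff": float(best["_age_diff"]),
            }
        )
    if not pairs:
        raise ValueError("no matched case-control pairs could be formed")
    n_cases_in = int((df["phenotype"] == "case").sum())
    n_controls_in = int((df["phenotype"] == "control").sum())
    return MatchResult(
        pairs=pd.DataFrame(pairs),
        n_cases_in=n_cases_in,
        n_controls_in=n_controls_in,
        n_excluded_restriction=int(n_in - eligible.sum()),
        dropped_cases=dropped,
    )
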