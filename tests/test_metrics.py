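"""Performance metrics, parallel testing, chi-square and selection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpmetrics as sm
from snpmetrics.metrics import (
    ALL_METRICS,
    DominantTable,
    chisq_allelic_vectorized,
)


class TestDominantTable:
    def test_direct_count_example(self):
        codes = np.array([1, 2, 0, 0, 0, 1])
        is_case = np.array([True, True, True, False, False, False])
        t = sm.dominant_table(codes, is_case)
        assert (t.tp, t.fn, t.fp, t.tn) == (2, 1, 1, 2)

    def test_all_carriers(self):
        t = sm.dominant_table(np.array([1, 2, 1, 2]), np.array([1, 1, 0, 0], bool))
        m = sm.performance_metrics(t)
        assert t.fn == t.tn == 0
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_missing_excluded_pairwise(self):
        codes = np.array([1, sm.MISSING, 0, 1])
        is_case = np.array([True, True, False, False])
        t = sm.dominant_table(codes, is_case)
        assert t.n_cases == 1 and t.n_controls == 2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sm.dominant_table(np.array([0, 1]), np.array([True, True]))

    def test_matches_enumeration_on_random_data(self, rng):
        for _ in range(20):
            codes = rng.integers(-1, 3, size=100)
            is_case = rng.random(100) < 0.5
            if not (is_case & (codes >= 0)).any() or not (~is_case & (codes >= 0)).any():
                continue
            t = sm.dominant_table(codes, is_case)
            tp = sum(1 for c, y in zip(codes, is_case) if c >= 1 and y)
            fp = sum(1 for c, y in zip(codes, is_case) if c >= 1 and not y)
            fn = sum(1 for c, y in zip(codes, is_case) if c == 0 and y)
            tn = sum(1 for c, y in zip(codes, is_case) if c == 0 and not y)
            assert (t.tp, t.fp, t.fn, t.tn) == (tp, fp, fn, tn)


class TestPerformanceMetrics:
    def test_stage1_apoc1_like_row(self):
        # sensitivity 0.56 with specificity 0.90 must give Youden 0.46
        t = DominantTable(tp=56, fn=44, fp=10, tn=90)
        m = sm.performance_metrics(t)
        assert m.sensitivity == pytest.approx(0.56)
        assert m.specificity == pytest.approx(0.90)
        assert m.youden == pytest.approx(0.46)

    def test_perfect_marker(self):
        m = sm.performance_metrics(DominantTable(tp=10, fn=0, fp=0, tn=10))
        assert m.sensitivity == m.specificity == m.accuracy == 1.0
        assert m.youden == 1.0
        assert np.isinf(m.dor)

    def test_degenerate_dor_is_undefined(self):
        m = sm.performance_metrics(DominantTable(tp=0, fn=5, fp=0, tn=5))
        assert np.isnan(m.dor)

    def test_formula_oracle_on_random_tables(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 200, size=4))
            m = sm.performance_metrics(DominantTable(tp, fp, fn, tn))
            assert m.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
            assert m.specificity == pytest.approx(tn / (fp + tn), abs=1e-12)
            assert m.ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
            assert m.npv == pytest.approx(tn / (fn + tn), abs=1e-12)
            assert m.dor == pytest.approx((tp / fp) / (fn / tn), rel=1e-12)
            assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn), abs=1e-12)
            # identities
            assert m.youden == pytest.approx(m.sensitivity + m.specificity - 1, abs=1e-12)
            n_case, n_ctrl = tp + fn, fp + tn
            assert m.accuracy == pytest.approx(
                (m.sensitivity * n_case + m.specificity * n_ctrl) / (n_case + n_ctrl),
                abs=1e-12,
            )
            assert m.dor == pytest.approx(
                (m.sensitivity * m.specificity)
                / ((1 - m.sensitivity) * (1 - m.specificity)),
                rel=1e-9,
            )
            # PPV/NPV consistent with Bayes' rule at the sample prevalence
            prev = n_case / (n_case + n_ctrl)
            assert m.ppv == pytest.approx(
                m.sensitivity * prev
                / (m.sensitivity * prev + (1 - m.specificity) * (1 - prev)),
                abs=1e-12,
            )


class TestNetMetrics:
    def test_stage1_apoe_apoc1_pairing(self):
        assert sm.net_sensitivity(0.50, 0.56) == pytest.approx(0.78)

    def test_absorbing_perfect_sensitivity(self):
        for x in (0.0, 0.3, 1.0):
            assert sm.net_sensitivity(1.0, x) == pytest.approx(1.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_identities_and_bounds(self, a, b):
        ns = sm.net_sensitivity(a, b)
        sp = sm.net_specificity(a, b)
        assert ns == pytest.approx(1 - (1 - a) * (1 - b), abs=1e-12)
        assert ns == pytest.approx(sm.net_sensitivity(b, a), abs=1e-12)
        assert sp == pytest.approx(sm.net_specificity(b, a), abs=1e-12)
        assert ns >= max(a, b) - 1e-12
        assert sp <= min(a, b) + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sm.net_sensitivity(1.2, 0.5)
        with pytest.raises(ValueError):
            sm.net_specificity(-0.1, 0.5)


class TestEmpiricalParallel:
    def test_never_positive_partner_is_identity(self, rng):
        a = rng.integers(0, 2, 200).astype(float)
        y = rng.random(200) < 0.4
        if not (a[y] >= 0).any():
            a[0] = 1
        base = sm.performance_metrics(sm.dominant_table(a.astype(int), y))
        combo = sm.empirical_parallel_test(a, np.zeros(200), y)
        assert combo.sensitivity == pytest.approx(base.sensitivity)
        assert combo.specificity == pytest.approx(base.specificity)

    def test_self_combination_is_identity(self, rng):
        a = rng.integers(0, 2, 200).astype(float)
        y = rng.random(200) < 0.5
        base = sm.performance_metrics(sm.dominant_table(a.astype(int), y))
        combo = sm.empirical_parallel_test(a, a, y)
        assert combo.sensitivity == pytest.approx(base.sensitivity)
        assert combo.specificity == pytest.approx(base.specificity)

    def test_formula_holds_under_conditional_independence(self, rng):
        """Empirical net metrics match the parallel-testing formula when the
        two markers are independent given disease status."""
        n = 10_000
        y = rng.random(n) < 0.4
        sens_a, sens_b, spec_a, spec_b = 0.5, 0.7, 0.9, 0.6
        a = np.where(y, rng.random(n) < sens_a, rng.random(n) < 1 - spec_a).astype(float)
        b = np.where(y, rng.random(n) < sens_b, rng.random(n) < 1 - spec_b).astype(float)
        emp_a = sm.performance_metrics(sm.dominant_table(a.astype(int), y))
        emp_b = sm.performance_metrics(sm.dominant_table(b.astype(int), y))
        combo = sm.empirical_parallel_test(a, b, y)
        pred_sens = sm.net_sensitivity(emp_a.sensitivity, emp_b.sensitivity)
        pred_spec = sm.net_specificity(emp_a.specificity, emp_b.specificity)
        n_case, n_ctrl = int(y.sum()), int((~y).sum())
        se_sens = np.sqrt(pred_sens * (1 - pred_sens) / n_case)
        se_spec = np.sqrt(pred_spec * (1 - pred_spec) / n_ctrl)
        assert abs(combo.sensitivity - pred_sens) < 3 * max(se_sens, 1e-3)
        assert abs(combo.specificity - pred_spec) < 3 * max(se_spec, 1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.empirical_parallel_test(np.zeros(3), np.zeros(4), np.zeros(3, bool))


def chisq_oracle(obs):
    """Textbook Pearson chi-square on a 2x2 table."""
    obs = np.asarray(obs, float)
    row = obs.sum(1, keepdims=True)
    col = obs.sum(0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


class TestChisq:
    def test_equal_carrier_fractions_give_null(self):
        codes = np.array([1, 0, 1, 0])
        y = np.array([1, 1, 0, 0], bool)
        s = sm.snp_chisq(codes, y, variant="dominant")
        assert s.chi2 == pytest.approx(0.0, abs=1e-12)
        assert s.p_value == pytest.approx(1.0)

    def test_matches_textbook_oracle(self, rng):
        from scipy import stats

        for _ in range(50):
            codes = rng.integers(0, 3, 80)
            y = rng.random(80) < 0.5
            if len(set(y)) < 2 or codes.sum() == 0 or codes.sum() == 160:
                continue
            s = sm.snp_chisq(codes, y, variant="allelic")
            a_case = codes[y].sum()
            a_ctrl = codes[~y].sum()
            obs = np.array(
                [
                    [a_case, 2 * y.sum() - a_case],
                    [a_ctrl, 2 * (~y).sum() - a_ctrl],
                ]
            )
            assert s.chi2 == pytest.approx(chisq_oracle(obs), abs=1e-10)
            assert s.p_value == pytest.approx(stats.chi2.sf(chisq_oracle(obs), 1), abs=1e-10)

    def test_vectorized_agrees_with_scalar(self, rng):
        mat = rng.integers(0, 3, size=(60, 12)).astype(np.int8)
        mat[rng.random(mat.shape) < 0.05] = sm.MISSING
        y = rng.random(60) < 0.5
        chi2, p = chisq_allelic_vectorized(mat, y)
        for j in range(12):
            s = sm.snp_chisq(mat[:, j], y, variant="allelic")
            if np.isnan(s.chi2):
                assert np.isnan(chi2[j])
            else:
                assert chi2[j] == pytest.approx(s.chi2, abs=1e-10)
                assert p[j] == pytest.approx(s.p_value, abs=1e-10)


class TestBonferroni:
    def test_genome_wide_magnitude(self):
        thr = sm.bonferroni_threshold(0.05, 500_941)
        assert thr == pytest.approx(9.98e-8, rel=1e-3)
        # rounding to one significant figure gives the conventional 1e-7
        assert float(f"{thr:.0e}") == pytest.approx(1e-7)

    def test_single_test_is_alpha(self):
        assert sm.bonferroni_threshold(0.05, 1) == 0.05

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.001, 0.999), st.integers(1, 10**7))
    def test_inverse_identity(self, alpha, m):
        assert sm.bonferroni_threshold(alpha, m) * m == pytest.approx(alpha)


def random_metric_frame(rng, n=20):
    df = pd.DataFrame(
        rng.random((n, len(ALL_METRICS))),
        columns=list(ALL_METRICS),
        index=[f"rs{i:03d}" for i in range(n)],
    )
    df["p_value"] = rng.random(n)
    return df


class TestMetricCountSelection:
    def test_dominating_snp_wins_with_full_count(self, rng):
        df = random_metric_frame(rng)
        df.loc["rs000", list(ALL_METRICS)] = 2.0  # above every other value
        res = sm.select_by_metric_counts(df, k=3)
        assert res.selected[0] == "rs000"
        assert res.table.loc["rs000", "metric_count"] == len(ALL_METRICS)

    def test_identical_rows_tie_break_by_id(self, rng):
        df = random_metric_frame(rng, n=5)
        df.loc["rs001"] = df.loc["rs003"]
        res = sm.select_by_metric_counts(df, k=5)
        t = res.table
        assert t.loc["rs001", "metric_count"] == t.loc["rs003", "metric_count"]
        assert list(t.index).index("rs001") < list(t.index).index("rs003")

    def test_counts_match_brute_force(self, rng):
        df = random_metric_frame(rng)
        res = sm.select_by_metric_counts(df, k=5)
        for snp in df.index:
            expected = sum(
                round(df.loc[snp, m], 6) == round(df[m], 6).max()
                for m in ALL_METRICS
            )
            assert res.table.loc[snp, "metric_count"] == expected

    def test_permutation_invariant(self, rng):
        df = random_metric_frame(rng)
        res1 = sm.select_by_metric_counts(df, k=5)
        res2 = sm.select_by_metric_counts(df.sample(frac=1, random_state=0), k=5)
        assert res1.selected == res2.selected

    def test_nan_metric_sits_out_comparison(self, rng):
        df = random_metric_frame(rng, n=6)
        df.loc["rs000", "dor"] = np.nan
        res = sm.select_by_metric_counts(df, k=2)
        assert res.table.loc["rs000", "metric_count"] == sum(
            round(df.loc["rs000", m], 6) == round(df[m], 6).max()
            for m in ALL_METRICS
            if m != "dor"
        )

    def test_too_few_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            sm.select_by_metric_counts(random_metric_frame(rng, n=3), k=5)


class TestPvalueSelection:
    def test_tie_at_cutoff_expands_selection(self):
        p = pd.Series(
            [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-2, 0.5],
            index=[f"rs{i}" for i in range(7)],
        )
        sel = sm.select_by_pvalue(p, k=5)
        assert len(sel) == 6  # two SNPs share the 5th-smallest value
        assert set(sel) == {"rs0", "rs1", "rs2", "rs3", "rs4", "rs5"}

    def test_distinct_values_give_exactly_k(self, rng):
        p = pd.Series(rng.permutation(10) / 100 + 1e-3, index=[f"s{i}" for i in range(10)])
        assert len(sm.select_by_pvalue(p, k=4)) == 4

    def test_matches_sort_oracle(self, rng):
        p = pd.Series(rng.random(50), index=[f"s{i}" for i in range(50)])
        sel = sm.select_by_pvalue(p, k=7)
        assert sel == list(p.sort_values().index[:7])
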