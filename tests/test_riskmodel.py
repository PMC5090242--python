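"""Logistic fits vs optimisation oracles, point derivation, AUC, LOOCV."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import snpmetrics as sm
from snpmetrics.riskmodel import round_half_up


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = sm.fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.coef_dict()["intercept"] == pytest.approx(math.log(30 / 70), abs=1e-8)

    def test_single_binary_predictor_is_log_or(self):
        # 2x2 table: exposed 20 case/10 ctrl, unexposed 15 case/55 ctrl
        x = np.array([1] * 30 + [0] * 70, float)
        y = np.array([1] * 20 + [0] * 10 + [1] * 15 + [0] * 55)
        fit = sm.fit_logistic(pd.DataFrame({"x": x}), y)
        expected = math.log((20 * 55) / (10 * 15))
        assert fit.coef_dict()["x"] == pytest.approx(expected, abs=1e-7)

    def test_matches_scipy_optimizer_oracle(self, rng):
        n = 50
        X = rng.normal(size=(n, 2))
        eta = 0.5 + X @ np.array([1.0, -0.7])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = sm.fit_logistic(pd.DataFrame(X, columns=["a", "b"]), y)

        Xd = np.column_stack([np.ones(n), X])

        def nll(beta):
            e = Xd @ beta
            return -np.sum(y * e - np.logaddexp(0, e))

        res = optimize.minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(fit.coef, res.x, atol=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_separation_is_flagged(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([0] * 10 + [1] * 10)
        with pytest.warns(UserWarning, match="separation"):
            fit = sm.fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.separation and not fit.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sm.fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), np.array([1, 1]))


def conditional_nll_oracle(beta, strata, X, y):
    """Conditional likelihood by explicit enumeration of case subsets."""
    beta = np.atleast_1d(beta)
    total = 0.0
    for s in np.unique(strata):
        m = strata == s
        Xs, ys = X[m], y[m]
        k = int(ys.sum())
        num = float(Xs[ys == 1].sum(axis=0) @ beta)
        den = [
            float(Xs[list(idx)].sum(axis=0) @ beta)
            for idx in itertools.combinations(range(len(ys)), k)
        ]
        total += num - float(np.logaddexp.reduce(den))
    return -total


class TestConditionalLogistic:
    def test_matched_pairs_equal_discordant_ratio(self, rng):
        # 1:1 pairs, binary exposure: beta = log(n10 / n01)
        n10, n01, n11, n00 = 20, 8, 5, 7
        rows = []
        sid = 0
        for count, (xc, xk) in zip(
            (n10, n01, n11, n00), ((1, 0), (0, 1), (1, 1), (0, 0))
        ):
            for _ in range(count):
                rows.append((sid, xc, 1))
                rows.append((sid, xk, 0))
                sid += 1
        df = pd.DataFrame(rows, columns=["stratum", "x", "y"])
        fit = sm.fit_conditional_logistic(
            df["stratum"], pd.DataFrame({"x": df["x"].astype(float)}), df["y"]
        )
        assert fit.coef_dict()["x"] == pytest.approx(math.log(n10 / n01), abs=1e-6)

    def test_equals_enumeration_oracle_on_small_strata(self, rng):
        strata, X, y = [], [], []
        for s in range(12):
            size = int(rng.integers(2, 7))
            k = int(rng.integers(1, size))
            xs = rng.normal(size=size)
            ys = np.zeros(size, int)
            ys[rng.choice(size, k, replace=False)] = 1
            strata += [s] * size
            X += list(xs)
            y += list(ys)
        strata = np.array(strata)
        X = np.array(X)[:, None]
        y = np.array(y)
        fit = sm.fit_conditional_logistic(strata, pd.DataFrame({"x": X[:, 0]}), y)
        res = optimize.minimize_scalar(
            lambda b: conditional_nll_oracle([b], strata, X, y), bounds=(-8, 8),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-4)
        # likelihood agreement at the fitted point, to high precision
        assert fit.loglik == pytest.approx(
            -conditional_nll_oracle(fit.coef, strata, X, y), abs=1e-8
        )

    def test_null_loglik_is_log_binomials(self, rng):
        strata = np.repeat(np.arange(6), 4)
        X = rng.normal(size=(24, 1))
        y = np.tile([1, 1, 0, 0], 6)
        expected = -6 * math.log(math.comb(4, 2))
        assert conditional_nll_oracle([0.0], strata, X, y) == pytest.approx(-expected)

    def test_uninformative_strata_dropped(self):
        strata = np.array([0, 0, 1, 1])
        X = pd.DataFrame({"x": [1.0, 0.0, 1.0, 1.0]})
        y = np.array([1, 0, 1, 1])  # stratum 1 has no control
        with pytest.warns(UserWarning, match="uninformative"):
            fit = sm.fit_conditional_logistic(strata, X, y)
        assert len(fit.coef) == 1


class TestDerivePoints:
    # the published final-model coefficients and their point values
    COEFS = {
        "age_gt75": 2.42,
        "female": 0.37,
        "edu_le6": 2.11,
        "apoe_e4": 0.91,
        "snp_carrier": 0.64,
    }

    def test_reference_scaled_points(self):
        pm = sm.derive_points(self.COEFS, "female")
        assert pm.points == {
            "age_gt75": 7,
            "female": 1,
            "edu_le6": 6,
            "apoe_e4": 2,
            "snp_carrier": 2,
        }
        assert pm.max_score == 18

    def test_round_half_up_not_ceiling(self):
        # 2.42/0.37 = 6.54 -> 7 either way, but 0.91/0.37 = 2.46 must give 2
        assert round_half_up(2.42 / 0.37) == 7
        assert round_half_up(0.91 / 0.37) == 2
        assert math.ceil(0.91 / 0.37) == 3  # the convention that contradicts

    def test_equal_coefficients_all_one_point(self):
        pm = sm.derive_points({"a": 0.5, "b": 0.5, "c": 0.5}, "b")
        assert set(pm.points.values()) == {1}

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="re-specify"):
            sm.derive_points({"a": 1.0, "b": -0.2}, "b")

    def test_exact_halves_round_up(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(1.5) == 2
        assert round_half_up(-0.5) == 0


class TestScoresAndGroups:
    def point_model(self):
        return sm.derive_points(TestDerivePoints.COEFS, "female")

    def test_all_risk_factors_give_max_score(self):
        pm = self.point_model()
        ind = pd.DataFrame({k: [1.0] for k in pm.entries})
        assert sm.total_score(ind, pm).iloc[0] == 18

    def test_no_risk_factors_give_zero(self):
        pm = self.point_model()
        ind = pd.DataFrame({k: [0.0] for k in pm.entries})
        assert sm.total_score(ind, pm).iloc[0] == 0

    def test_grouping_matches_interval_oracle(self, rng):
        scores = rng.integers(0, 19, 200)
        groups = sm.assign_groups(scores)
        for s, g in zip(scores, groups):
            expected = 0 if s <= 6 else (1 if s <= 11 else 2)
            assert g == expected

    def test_out_of_range_score_flagged(self):
        assert sm.assign_groups(np.array([25.0]))[0] == -1

    def test_missing_predictor_rejected(self):
        pm = self.point_model()
        with pytest.raises(KeyError):
            sm.total_score(pd.DataFrame({"age_gt75": [1.0]}), pm)


class TestGroupAorTrend:
    def test_matches_plain_logistic_oracle(self, rng):
        groups = rng.integers(0, 3, 400)
        eta = -1.5 + 1.0 * groups
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(int)
        g = sm.group_aor_and_trend(groups, y)
        X = pd.DataFrame(
            {"group1": (groups == 1).astype(float), "group2": (groups == 2).astype(float)}
        )
        oracle = sm.fit_logistic(X, y)
        assert g.aor.loc["group1", "or"] == pytest.approx(
            math.exp(oracle.coef_dict()["group1"]), rel=1e-6
        )
        assert g.aor.loc["group2", "or"] == pytest.approx(
            math.exp(oracle.coef_dict()["group2"]), rel=1e-6
        )

    def test_monotone_scores_give_monotone_aors(self, rng):
        groups = rng.integers(0, 3, 600)
        eta = -2.0 + 1.3 * groups
        y = (rng.random(600) < 1 / (1 + np.exp(-eta))).astype(int)
        g = sm.group_aor_and_trend(groups, y)
        assert 1.0 < g.aor.loc["group1", "or"] < g.aor.loc["group2", "or"]
        assert g.trend_p < 1e-6

    def test_null_scores_give_null_aors(self, rng):
        groups = rng.integers(0, 3, 500)
        y = (rng.random(500) < 0.3).astype(int)
        g = sm.group_aor_and_trend(groups, y)
        for grp in ("group1", "group2"):
            assert g.aor.loc[grp, "ci_low"] < 1.0 < g.aor.loc[grp, "ci_high"]
        assert g.trend_p > 0.001


def auc_pairwise_oracle(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAucDelong:
    def test_perfect_separation(self):
        auc, ci, _ = sm.auc_delong(np.array([1, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1]))
        assert auc == 1.0
        assert ci[1] == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        auc, _, se = sm.auc_delong(scores, labels)
        assert abs(auc - 0.5) < 3 * se

    def test_equals_pairwise_oracle_with_ties(self, rng):
        scores = rng.integers(0, 10, 200).astype(float)  # heavy ties
        labels = (rng.random(200) < 0.4).astype(int)
        auc, _, _ = sm.auc_delong(scores, labels)
        assert auc == pytest.approx(auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300)
        labels = (rng.random(300) < 0.3).astype(int)
        auc, _, _ = sm.auc_delong(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sm.auc_delong(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_delong_se_matches_structural_oracle(self, rng):
        scores = rng.normal(size=120) + np.repeat([0, 1], 60)
        labels = np.repeat([0, 1], 60)
        _, _, se = sm.auc_delong(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        v10 = psi.mean(axis=1)
        v01 = psi.mean(axis=0)
        se_oracle = math.sqrt(v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg))
        assert se == pytest.approx(se_oracle, abs=1e-12)


class TestLoocv:
    def make_data(self, rng, n=80, informative=True):
        X = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        eta = (1.5 * X["x"] if informative else 0.0) - 0.2
        y = (rng.random(n) < 1 / (1 + np.exp(-np.asarray(eta, float)))).astype(int)
        return X, y

    def test_corrected_equals_cross_validated(self, rng):
        X, y = self.make_data(rng)
        cv = sm.loocv_optimism(X, y)
        assert cv.corrected_auc == pytest.approx(cv.cv_auc, abs=1e-12)
        assert cv.optimism == pytest.approx(cv.apparent_auc - cv.cv_auc, abs=1e-12)

    def test_deterministic_under_fixed_data(self, rng):
        X, y = self.make_data(rng)
        a = sm.loocv_optimism(X, y)
        b = sm.loocv_optimism(X, y)
        assert a.apparent_auc == b.apparent_auc
        assert a.cv_auc == b.cv_auc

    def test_uninformative_model_has_large_optimism(self, rng):
        X, y = self.make_data(rng, informative=False)
        cv = sm.loocv_optimism(X, y)
        # apparent AUC of pure noise predictors sits above 0.5, the
        # cross-validated AUC does not follow it
        assert cv.optimism > 0
        assert cv.cv_auc < cv.apparent_auc
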