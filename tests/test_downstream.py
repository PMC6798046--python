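"""Gene-pair correlation, coexpression survival, and covariate regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigmeta.downstream import (
    CoxSeparationError,
    SurvivalCohort,
    coexpression_groups,
    cox_hr,
    cox_partial_loglik,
    fit_linear_model,
    km_curve_data,
    logrank,
    mlr_covariates,
    pearson,
    survival_analysis,
)
from sigmeta.simulate import generate_survival_cohort


def cohort_from(times, events, groups):
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(len(times))],
            "expr_a": 0.0,
            "expr_b": 0.0,
            "time": times,
            "event": events,
        }
    )
    return SurvivalCohort(df), pd.Series(groups, index=df.index)


class TestPearson:
    def test_perfect_linearity(self):
        assert pearson([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)

    def test_hand_worked_moments(self):
        assert pearson([1, 2, 3], [1, 3, 2]).r == pytest.approx(0.5)

    def test_affine_invariance_with_positive_slope(self):
        rng = np.random.default_rng(41)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = pearson(x, y).r
        assert pearson(3.2 * x + 7, y).r == pytest.approx(base, abs=1e-12)
        assert pearson(x, 0.5 * y - 2).r == pytest.approx(base, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            pearson([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            pearson([1, 2], [3, 4])


class TestCoexpressionGroups:
    def make(self, a, b):
        return SurvivalCohort(
            pd.DataFrame(
                {
                    "patient_id": [f"p{i}" for i in range(len(a))],
                    "expr_a": a,
                    "expr_b": b,
                    "time": 1.0,
                    "event": 1,
                }
            )
        )

    def test_median_split(self):
        labels = coexpression_groups(self.make([1, 2, 3, 4], [1, 2, 3, 4]))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_gene_order_symmetry(self):
        a, b = [1, 5, 2, 4], [3, 1, 4, 2]
        assert list(coexpression_groups(self.make(a, b))) == list(
            coexpression_groups(self.make(b, a))
        )

    def test_score_at_median_goes_low(self):
        labels = coexpression_groups(self.make([1, 2, 2, 4, 5], [1, 2, 2, 4, 5]))
        assert labels.iloc[1] == "low" and labels.iloc[2] == "low"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            coexpression_groups(self.make([2, 2, 2, 2], [3, 3, 3, 3]))
        with pytest.raises(ValueError, match="4 patients"):
            coexpression_groups(self.make([1, 2, 3], [1, 2, 3]))


class TestLogrank:
    def test_hand_worked_fixture(self):
        cohort, labels = cohort_from([1, 2, 3, 4], [1, 1, 1, 1], ["high"] * 2 + ["low"] * 2)
        chi2, p = logrank(cohort, labels)
        assert chi2 == pytest.approx(49 / 17, abs=1e-3)
        assert p == pytest.approx(0.0895, abs=1e-3)

    def test_identical_groups_give_null_statistic(self):
        cohort, labels = cohort_from(
            [1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], ["high"] * 3 + ["low"] * 3
        )
        chi2, p = logrank(cohort, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(43)
        times = rng.exponential(1, 20)
        events = rng.integers(0, 2, 20)
        events[0] = 1
        g = ["high"] * 10 + ["low"] * 10
        cohort, labels = cohort_from(times, events, g)
        flipped = labels.map({"high": "low", "low": "high"})
        assert logrank(cohort, labels)[0] == pytest.approx(
            logrank(cohort, flipped)[0], abs=1e-9
        )

    def test_errors(self):
        cohort, labels = cohort_from([1, 2], [1, 1], ["high", "high"])
        with pytest.raises(ValueError, match="non-empty"):
            logrank(cohort, labels)
        cohort, labels = cohort_from([1, 2], [0, 0], ["high", "low"])
        with pytest.raises(ValueError, match="events"):
            logrank(cohort, labels)


def grid_search_beta(cohort, labels, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force partial-likelihood oracle over a dense beta grid."""
    d = cohort.data
    time = d["time"].to_numpy(float)
    event = d["event"].to_numpy(int)
    x = (labels == "high").to_numpy(int)
    grid = np.arange(lo, hi + step, step)
    ll = [cox_partial_loglik(b, time, event, x) for b in grid]
    return float(grid[int(np.argmax(ll))])


class TestCoxHR:
    def test_hand_fixture_matches_grid_oracle(self):
        cohort, labels = cohort_from([1, 3, 2, 4], [1, 1, 1, 1], ["low", "low", "high", "high"])
        hr, ci, p = cox_hr(cohort, labels)
        beta_grid = grid_search_beta(cohort, labels)
        assert hr == pytest.approx(np.exp(beta_grid), abs=1e-3)
        assert hr == pytest.approx(0.39, abs=5e-3)
        assert ci[0] < hr < ci[1]

    def test_random_fixtures_match_grid_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(5):
            n = 30
            g = ["high"] * 15 + ["low"] * 15
            times = rng.exponential(np.where(np.array(g) == "high", 0.5, 1.0))
            events = rng.random(n) < 0.8
            events[:2] = True
            cohort, labels = cohort_from(times, events.astype(int), g)
            hr, _, _ = cox_hr(cohort, labels)
            assert np.log(hr) == pytest.approx(
                grid_search_beta(cohort, labels), abs=1e-3
            )

    def test_exchangeable_groups_give_unit_hazard(self):
        cohort, labels = cohort_from(
            [1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], ["high"] * 3 + ["low"] * 3
        )
        hr, ci, _ = cox_hr(cohort, labels)
        assert hr == pytest.approx(1.0, abs=1e-9)

    def test_matches_lifelines_cox_fit(self):
        """Cross-check the hand-rolled partial likelihood against lifelines."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(53)
        n = 80
        g = ["high"] * 40 + ["low"] * 40
        times = rng.exponential(np.where(np.array(g) == "high", 0.4, 1.0))
        cohort, labels = cohort_from(times, [1] * n, g)
        hr, ci, _ = cox_hr(cohort, labels)
        df = pd.DataFrame({"t": times, "e": 1, "x": (labels == "high").astype(int)})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.log(hr) == pytest.approx(cph.params_["x"], abs=1e-3)

    def test_separation_reported_cleanly(self):
        cohort, labels = cohort_from(
            [1, 2, 3, 4], [1, 1, 1, 1], ["high", "high", "low", "low"]
        )
        with pytest.raises(CoxSeparationError):
            cox_hr(cohort, labels)

    def test_too_few_events_rejected(self):
        cohort, labels = cohort_from([1, 2, 3, 4], [1, 0, 0, 0], ["high"] * 2 + ["low"] * 2)
        with pytest.raises(ValueError, match="2 events"):
            cox_hr(cohort, labels)


class TestSurvivalAnalysis:
    def test_end_to_end_on_synthetic_cohort(self):
        cohort = generate_survival_cohort(n=120, hr=2.5, censor_rate=0.1, seed=61)
        r = survival_analysis(cohort)
        assert r.n_high + r.n_low == 120
        assert r.hr > 1.0
        assert 0 <= r.p <= 1 and 0 <= r.cox_p <= 1

    def test_km_curve_data_has_both_groups(self):
        cohort = generate_survival_cohort(n=40, hr=2.0, seed=62)
        labels = coexpression_groups(cohort)
        km = km_curve_data(cohort, labels)
        assert set(km["group"]) == {"high", "low"}
        assert ((km["survival"] >= 0) & (km["survival"] <= 1)).all()


def normal_equations_ols(y, X):
    """Independent OLS oracle: solve X'X b = X'y and t-test the slopes."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, p


class TestLinearModel:
    def test_hand_worked_single_factor(self):
        fit = fit_linear_model([1, 2, 2, 3], pd.DataFrame({"x": [1, 2, 3, 4]}))
        assert fit.params["x"] == pytest.approx(0.6)
        assert fit.bse["x"] == pytest.approx(0.1414, abs=2e-4)
        assert fit.pvalues["x"] == pytest.approx(0.051, abs=1e-3)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(67)
        for _ in range(20):
            n, k = int(rng.integers(10, 50)), int(rng.integers(1, 6))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            fit = fit_linear_model(y, pd.DataFrame(X, columns=[f"x{i}" for i in range(k)]))
            beta, se, p = normal_equations_ols(y, X)
            assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-10)
            assert fit.bse.to_numpy() == pytest.approx(se, abs=1e-10)
            assert fit.pvalues.to_numpy()[1:] == pytest.approx(p[1:], abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10]})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear_model([1, 2, 3, 4, 5], X)


class TestMlrCovariates:
    SIZES = [27, 99, 84, 69, 268, 99, 38, 65, 148, 24, 94, 20]

    def table(self, lfc, countries, sizes=None, dates=None):
        n = len(lfc)
        return pd.DataFrame(
            {
                "gene": "G",
                "study_id": [f"s{i}" for i in range(n)],
                "lfc": lfc,
                "sample_size": sizes or self.SIZES[:n],
                "country": countries,
                "date": dates or list(range(2006, 2006 + n)),
            }
        )

    def test_factors_reported_with_ci_and_p(self):
        rng = np.random.default_rng(71)
        t = self.table(
            list(rng.normal(size=10)), ["A"] * 5 + ["B"] * 5
        )
        m = mlr_covariates(t)
        assert set(m.factors) == {"sample_size", "country", "date"}
        for f in m.factors.values():
            assert 0 <= f.p <= 1
            assert len(f.ci95) == len(f.coef)

    def test_country_partial_f_detects_planted_shift(self):
        rng = np.random.default_rng(73)
        countries = ["A"] * 6 + ["B"] * 6
        lfc = list(rng.normal(0, 0.1, 6)) + list(rng.normal(1.0, 0.1, 6))
        m = mlr_covariates(self.table(lfc, countries))
        assert m.factors["country"].p < 0.01

    def test_constant_response_degenerate_convention(self):
        m = mlr_covariates(self.table([1.0] * 8, ["A"] * 4 + ["B"] * 4))
        for f in m.factors.values():
            assert f.p == 1.0
            assert all(c == 0.0 for c in f.coef)

    def test_single_country_rejected(self):
        with pytest.raises(ValueError, match="2 distinct countries"):
            mlr_covariates(self.table([1, 2, 3, 4, 5, 6], ["A"] * 6))

    def test_collinear_covariates_rejected(self):
        t = self.table(
            [1, 2, 3, 4, 5, 6],
            ["A", "B"] * 3,
            sizes=[10, 20, 30, 40, 50, 60],
            dates=[10, 20, 30, 40, 50, 60],
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            mlr_covariates(t)
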