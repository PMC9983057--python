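import numpy as np
import pytest
from scipy.optimize import bisect
from scipy.special import expit, logit

import ipsi
from ipsi.nuisance import ConstantLearner, build_design, fractional_logistic_fit


class TestFractionalLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0, 0, 0, 0] * 5)
        fit = fractional_logistic_fit(np.ones((20, 1)), y)
        assert fit.theta[0] == pytest.approx(logit(0.25), abs=1e-9)

    def test_weighted_mean_closed_form(self):
        rng = np.random.default_rng(4)
        y = rng.random(30)
        w = rng.random(30) + 0.1
        fit = fractional_logistic_fit(np.ones((30, 1)), y, weights=w)
        assert expit(fit.theta[0]) == pytest.approx(np.sum(w * y) / np.sum(w),
                                                    abs=1e-10)

    def test_offset_fluctuation_matches_bisection_oracle(self):
        # single free intercept with a fixed offset on a 5-row fixture
        off = np.array([-0.7, 0.2, 1.1, -0.3, 0.5])
        y = np.array([0.9, 0.4, 1.0, 0.1, 0.6])
        w = np.array([1.0, 2.0, 0.5, 1.5, 1.0])

        def score(g):
            return float(np.sum(w * (y - expit(off + g))))

        oracle = bisect(score, -10, 10, xtol=1e-13)
        fit = fractional_logistic_fit(np.ones((5, 1)), y, weights=w,
                                      offset=off)
        assert fit.theta[0] == pytest.approx(oracle, abs=1e-8)

    def test_matches_logistic_mle(self):
        # binary response, no weights/offset: equals the logistic MLE from an
        # independent implementation (statsmodels Newton)
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(400), rng.standard_normal((400, 2))])
        y = (rng.random(400) < expit(X @ [0.3, -0.8, 0.5])).astype(float)
        ours = fractional_logistic_fit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(ours.theta, ref.params, atol=1e-6)

    @pytest.mark.parametrize("seed", range(25))
    def test_score_solved_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 80)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2)),
                             rng.integers(0, 2, n)])
        y = rng.random(n)
        w = rng.random(n) * 3
        w[rng.integers(0, n)] = 0.0
        off = rng.standard_normal(n) * 0.5
        fit = fractional_logistic_fit(X, y, weights=w, offset=off)
        mu = expit(off + X @ fit.theta)
        score = X.T @ (w * (y - mu))
        assert np.max(np.abs(score)) < 1e-8

    def test_response_domain_error(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fractional_logistic_fit(np.ones((3, 1)), np.array([0.5, 1.2, 0.1]))

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError, match="positive weight"):
            fractional_logistic_fit(np.ones((3, 1)), np.full(3, 0.5),
                                    weights=np.zeros(3))

    def test_constant_response_converges(self):
        fit = fractional_logistic_fit(np.ones((10, 1)), np.ones(10))
        assert expit(fit.theta[0]) == pytest.approx(1.0, abs=1e-9)


class TestDesign:
    def test_products_and_intercept(self):
        cols = {"a": np.array([1.0, 2]), "b": np.array([3.0, 4])}
        X = build_design(cols, "a + b + a:b")
        assert np.array_equal(X, [[1, 1, 3, 3], [1, 2, 4, 8]])

    def test_intercept_only(self):
        X = build_design({"a": np.zeros(3)}, "1")
        assert X.shape == (3, 1)

    def test_saturated_formula_term_count(self):
        f = ipsi.saturated_formula(["a", "b", "c"])
        assert len(f.split("+")) == 7  # 2^3 - 1 non-constant terms


class TestTreatmentModels:
    def test_coefficient_recovery_study1(self):
        # A_j ~ Ber{expit(-1 - 2 L* - L1 + L2 + 2 A_lag)}: the fitted
        # coefficient on L* at j=0 recovers -2 within 3 standard errors
        p = ipsi.simulate_study1(100_000, 11)
        models, pi1 = ipsi.fit_treatment_models(p, "lstar + L1 + L2 + Alag")
        risk = p.at_risk(1)  # j=1: the treatment lag varies
        X = build_design(p.frame(1), "lstar + L1 + L2 + Alag", mask=risk)
        mu = expit(X @ models[1].fit.theta)
        H = X.T @ (X * (mu * (1 - mu))[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(H)))[1]
        assert abs(models[1].fit.theta[1] - (-2.0)) < 3 * se
        assert np.all((pi1[risk, 1] > 0) & (pi1[risk, 1] < 1))

    def test_censoring_coefficient_recovery_study1(self):
        # C_{j+1} ~ Ber{expit(-2 + L1_j - L2_j)}: coefficient on L1 is +1
        p = ipsi.simulate_study1(100_000, 13)
        models, chaz = ipsi.fit_censoring_models(p, "L1 + L2")
        X = build_design(p.frame(0), "L1 + L2")
        mu = expit(X @ models[0].fit.theta)
        H = X.T @ (X * (mu * (1 - mu))[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(H)))[1]
        assert abs(models[0].fit.theta[1] - 1.0) < 3 * se

    def test_no_censoring_gives_zero_hazard(self):
        p = ipsi.simulate_study1(500, 3, censoring=False)
        _, chaz = ipsi.fit_censoring_models(p, "L1 + L2")
        assert np.all(chaz == 0)

    def test_degenerate_response_names_interval(self):
        p = ipsi.simulate_study1(200, 5, censoring=False)
        p.A[:, :] = np.where(np.isnan(p.A), np.nan, 1.0)
        with pytest.raises(ipsi.DegenerateFitError, match="j=0"):
            ipsi.fit_treatment_models(p, "lstar")

    def test_absorbing_excludes_already_treated(self):
        p = ipsi.simulate_study2(800, 5)
        models, pi1 = ipsi.fit_treatment_models(p, "lstar + L1",
                                                absorbing=True)
        for j in range(1, p.J):
            risk = p.at_risk(j)
            on = risk & (p.A[:, j - 1] == 1)
            assert np.all(pi1[on, j] == 1.0)


class TestCVStack:
    def _problem(self, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        y = (rng.random(n) < expit(X @ [1.0, -1.0, 0.5])).astype(float)
        return X, y

    def test_weights_on_simplex(self):
        learners = [ipsi.GLMLearner(), ConstantLearner()]
        for seed in range(30):
            X, y = self._problem(80, seed)
            stack = ipsi.cv_stack(learners, X, y, folds=4, seed=seed)
            assert np.all(stack.weights >= 0)
            assert stack.weights.sum() == pytest.approx(1.0)

    def test_true_model_dominates_constant(self):
        X, y = self._problem(5000, 0)
        stack = ipsi.cv_stack([ipsi.GLMLearner(), ConstantLearner()], X, y,
                              folds=5, seed=0)
        assert stack.weights[0] > 0.9

    def test_identical_candidates_invariant_prediction(self):
        X, y = self._problem(200, 1)
        stack = ipsi.cv_stack([ipsi.GLMLearner(), ipsi.GLMLearner()], X, y,
                              folds=4, seed=3)
        single = ipsi.GLMLearner().fit(X, y)
        assert np.allclose(stack.predict(X), single.predict(X), atol=1e-9)

    def test_single_learner_weight_one(self):
        X, y = self._problem(100, 2)
        stack = ipsi.cv_stack([ipsi.GLMLearner()], X, y)
        assert np.array_equal(stack.weights, [1.0])

    def test_no_learners_error(self):
        with pytest.raises(ValueError):
            ipsi.cv_stack([], np.ones((5, 1)), np.ones(5))

    def test_discrete_selection_picks_best(self):
        X, y = self._problem(2000, 4)
        stack = ipsi.cv_stack([ipsi.GLMLearner(), ConstantLearner()], X, y,
                              folds=5, seed=1, discrete=True)
        assert np.array_equal(np.sort(stack.weights), [0.0, 1.0])
        assert stack.weights[0] == 1.0


def test_prediction_clipping_logged(caplog):
    import logging

    p = ipsi.simulate_study1(300, 3, censoring=False)
    with caplog.at_level(logging.WARNING, logger="ipsi.nuisance"):
        from ipsi.nuisance import clip_probability

        clip_probability(np.array([0.5, 1e-9, 0.2]))
    assert "clipped" in caplog.text
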