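import numpy as np
import pytest

import ipsi
from conftest import J2_SAT_OUTCOME, J2_SAT_TREATMENT, manual_panel


def _nuisance(pi1, chaz=None):
    if chaz is None:
        chaz = np.zeros_like(pi1)
    return ipsi.NuisanceFit(pi1=pi1, censoring_hazard=chaz)


class TestCumulativeWeights:
    def test_hand_product_single_subject(self, spec05):
        # one subject, J=2, treated with indication at both intervals:
        # weight = prod_j q(1)/pi(1) with q(1) = 0.5 + 0.5 pi(1)
        panel = manual_panel([[1.0, 1.0]], [[1.0, 1.0]], np.zeros((1, 3)),
                             np.ones((1, 3)))
        pi1 = np.array([[0.4, 0.25]])
        w = ipsi.cumulative_weights(panel, spec05, _nuisance(pi1), 1)
        expected = ((0.5 + 0.5 * 0.4) / 0.4) * ((0.5 + 0.5 * 0.25) / 0.25)
        assert w[0] == pytest.approx(expected, abs=1e-12)

    def test_delta_one_all_ones(self):
        p = ipsi.simulate_study1(400, 21, censoring=False)
        nuis = ipsi.fit_nuisance(p, treatment_formulas="lstar + L1 + L2 + "
                                 "Alag", model_censoring=False)
        spec = ipsi.multiplicative_shift(1.0)
        for j in range(p.J):
            w = ipsi.cumulative_weights(p, spec, nuis, j)
            risk = p.at_risk(j)
            assert np.allclose(w[risk], 1.0, atol=1e-12)
            assert np.all(w[~risk] == 0.0)

    def test_censored_subject_weight_zero_onward(self, spec05):
        C = np.array([[0.0, 0, 1], [0, 0, 0]])
        Y = np.array([[1.0, 1, np.nan], [1, 1, 1]])
        panel = manual_panel(np.ones((2, 2)), np.ones((2, 2)), C, Y)
        pi1 = np.full((2, 2), 0.5)
        w = ipsi.cumulative_weights(panel, spec05, _nuisance(pi1), 1)
        assert w[0] == 0.0 and w[1] > 0

    def test_censoring_weights_fold_in(self, spec05):
        panel = manual_panel([[1.0]], [[1.0]], np.zeros((1, 2)),
                             np.ones((1, 2)))
        nuis = _nuisance(np.array([[0.5]]), chaz=np.array([[0.2]]))
        w = ipsi.cumulative_weights(panel, spec05, nuis, 0)
        assert w[0] == pytest.approx((0.75 / 0.5) / 0.8)


class TestICE:
    def test_saturated_equals_empirical_plugin(self, j2_law, spec05):
        panel = ipsi.sample_discrete_law(j2_law, 2500, 17)
        plug = ipsi.exact_gformula(ipsi.empirical_law(panel), spec05)
        ice = ipsi.ice_estimate(panel, spec05, J2_SAT_OUTCOME)
        assert ice.psi_hat == pytest.approx(plug, abs=1e-10)

    def test_j1_saturated_matches_example1_identity(self, j1_law, spec05):
        # psi-hat = sum_l [sum_a m-hat(a,l) q-hat(a|l)] p-hat(l)
        panel = ipsi.sample_discrete_law(j1_law, 800, 3)
        nuis = ipsi.fit_nuisance(panel, treatment_formulas="L",
                                 model_censoring=False)
        ice = ipsi.wice_estimate(panel, spec05, nuis, "A + L + A:L")
        L, A, Y1 = panel.covariates["L"][:, 0], panel.A[:, 0], panel.Y[:, 1]
        direct = 0.0
        for l in (0.0, 1.0):
            pl = np.mean(L == l)
            f1 = np.mean(A[L == l] == 1)
            for a in (0.0, 1.0):
                m = np.mean(Y1[(L == l) & (A == a)])
                q = (1 - 0.5) * a + 0.5 * (f1 if a == 1 else 1 - f1)
                direct += pl * m * q
        assert ice.psi_hat == pytest.approx(direct, abs=1e-10)

    def test_all_survivors_gives_one(self, spec05):
        panel = manual_panel(np.ones((20, 2)),
                             np.column_stack([np.ones(20), np.zeros(20)]),
                             np.zeros((20, 3)), np.ones((20, 3)))
        res = ipsi.ice_estimate(panel, spec05, "lstar")
        assert res.psi_hat == pytest.approx(1.0, abs=1e-9)

    def test_empty_risk_set_contributes_zero(self, spec05):
        Y = np.ones((4, 3))
        Y[:, 2] = 0  # everyone dies in the second interval
        Y[2:, 1] = 0  # half die in the first
        panel = manual_panel(np.ones((4, 2)), np.zeros((4, 2)),
                             np.zeros((4, 3)), Y)
        res = ipsi.ice_estimate(panel, spec05, "1")
        assert res.psi_hat == pytest.approx(0.0, abs=1e-9)


class TestIPW:
    def test_weighted_mean_fixture(self, spec05):
        # 4 subjects, J=1, hand weights {2,1,1,0} (the last censored),
        # Y_1 = {1,1,0,-}: Upsilon_0 = (2+1)/(2+1+1) = 3/4; the middle two
        # have no indication, so their q/pi ratio is exactly one
        C = np.zeros((4, 2)); C[3, 1] = 1.0
        Y = np.array([[1.0, 1], [1, 1], [1, 0], [1, np.nan]])
        lstar = np.array([[1.0], [0.0], [0.0], [1.0]])
        panel = manual_panel(lstar, np.ones((4, 1)), C, Y)
        pi1 = np.array([[1 / 3], [0.5], [0.5], [0.5]])  # ratios 2,1,1,-
        res = ipsi.ipw_estimate(panel, spec05, _nuisance(pi1))
        assert res.psi_hat == pytest.approx(0.75, abs=1e-12)

    def test_delta_one_no_censoring_is_empirical_fraction(self):
        p = ipsi.simulate_study1(600, 31, censoring=False)
        nuis = ipsi.fit_nuisance(p, treatment_formulas="lstar + L1 + L2 + "
                                 "Alag", model_censoring=False)
        res = ipsi.ipw_estimate(p, ipsi.multiplicative_shift(1.0), nuis)
        assert res.psi_hat == pytest.approx(np.mean(p.Y[:, 5] == 1),
                                            abs=1e-10)

    def test_equals_intercept_only_wice(self, j2_law, spec05):
        worst = 0.0
        for seed in range(50):
            panel = ipsi.sample_discrete_law(j2_law, 300, 100 + seed)
            nuis = ipsi.fit_nuisance(panel, treatment_formulas=J2_SAT_TREATMENT,
                                     model_censoring=False)
            ipw = ipsi.ipw_estimate(panel, spec05, nuis).psi_hat
            wice = ipsi.wice_estimate(panel, spec05, nuis, "1").psi_hat
            worst = max(worst, abs(ipw - wice))
        assert worst < 1e-10


class TestWICE:
    def test_saturated_equals_empirical_plugin(self, j2_law, spec05):
        panel = ipsi.sample_discrete_law(j2_law, 2500, 17)
        nuis = ipsi.fit_nuisance(panel, treatment_formulas=J2_SAT_TREATMENT,
                                 model_censoring=False)
        plug = ipsi.exact_gformula(ipsi.empirical_law(panel), spec05)
        wice = ipsi.wice_estimate(panel, spec05, nuis, J2_SAT_OUTCOME)
        assert wice.psi_hat == pytest.approx(plug, abs=1e-10)

    def test_delta_one_equals_ice(self):
        p = ipsi.simulate_study1(800, 41, censoring=False)
        forms = ipsi.misspecified_formulas("all_correct")
        nuis = ipsi.fit_nuisance(p, treatment_formulas=forms["treatment"],
                                 model_censoring=False)
        spec = ipsi.multiplicative_shift(1.0)
        w = ipsi.wice_estimate(p, spec, nuis, forms["outcome"])
        i = ipsi.ice_estimate(p, spec, forms["outcome"])
        assert w.psi_hat == pytest.approx(i.psi_hat, abs=1e-12)

    def test_odds_shift_refused(self, j2_law):
        panel = ipsi.sample_discrete_law(j2_law, 200, 1)
        nuis = ipsi.fit_nuisance(panel, treatment_formulas="L",
                                 model_censoring=False)
        with pytest.raises(ipsi.NonCanonicalInterventionError):
            ipsi.wice_estimate(panel, ipsi.odds_shift(2.0), nuis, "L")

    def test_sample_bounded(self, j2_law):
        # estimates stay in [0, 1] whatever the weights do
        for seed in range(200):
            rng = np.random.default_rng(seed)
            panel = ipsi.sample_discrete_law(j2_law, 60, seed)
            delta = rng.uniform(0.05, 1.0)
            spec = ipsi.multiplicative_shift(delta)
            nuis = ipsi.fit_nuisance(panel, treatment_formulas="L + Alag",
                                     model_censoring=False)
            for est in (
                ipsi.wice_estimate(panel, spec, nuis, "A + L"),
                ipsi.ice_estimate(panel, spec, "A + L"),
            ):
                assert -1e-12 <= est.psi_hat <= 1 + 1e-12

    def test_multiple_robustness_j2_configurations(self, j2_law, spec05):
        """J+1 robustness on a J=2 design: unbiased whenever the outcome
        models are correct from interval k on and the treatment models are
        correct before k, for k = 0, 1, 2."""
        truth = ipsi.exact_gformula(j2_law, spec05)
        wrong = "1"  # intercept-only working model is badly misspecified
        configs = {
            0: (['1', '1'], J2_SAT_OUTCOME),
            1: ([J2_SAT_TREATMENT[0], wrong], [wrong, J2_SAT_OUTCOME[1]]),
            2: (J2_SAT_TREATMENT, [wrong, wrong]),
        }
        for k, (tf, of) in configs.items():
            ests = []
            for rep in range(60):
                panel = ipsi.sample_discrete_law(j2_law, 4000, 50_000 + rep)
                nuis = ipsi.fit_nuisance(panel, treatment_formulas=tf,
                                         model_censoring=False)
                ests.append(ipsi.wice_estimate(panel, spec05, nuis,
                                               of).psi_hat)
            ests = np.asarray(ests)
            bias = ests.mean() - truth
            mcse = ests.std(ddof=1) / np.sqrt(len(ests))
            assert abs(bias) < 3 * mcse, f"config k={k}: {bias} vs {mcse}"


class TestBootstrap:
    def test_degenerate_data_zero_width(self, spec05):
        panel = manual_panel(np.ones((30, 1)), np.ones((30, 1)),
                             np.zeros((30, 2)), np.ones((30, 2)))
        ci = ipsi.bootstrap_ci(
            lambda p: ipsi.ice_estimate(p, spec05, "1"), panel, B=50, seed=1)
        assert ci.lower == pytest.approx(1.0, abs=1e-9)
        assert ci.upper == pytest.approx(1.0, abs=1e-9)

    def test_reproducible_and_percentile(self, j2_law, spec05):
        panel = ipsi.sample_discrete_law(j2_law, 200, 5)
        est = lambda p: ipsi.ice_estimate(p, spec05, "A + L")  # noqa: E731
        c1 = ipsi.bootstrap_ci(est, panel, B=40, seed=11)
        c2 = ipsi.bootstrap_ci(est, panel, B=40, seed=11)
        assert np.array_equal(c1.estimates, c2.estimates)
        lo, hi = np.percentile(c1.estimates, [2.5, 97.5])
        assert (c1.lower, c1.upper) == (pytest.approx(lo), pytest.approx(hi))

    def test_b_floor(self, toy_panel, spec05):
        with pytest.raises(ValueError):
            ipsi.bootstrap_ci(lambda p: 0.5, toy_panel, B=1)

    def test_failing_replicates_error(self, toy_panel):
        def boom(p):
            raise RuntimeError("fit failed")

        with pytest.raises(ipsi.EstimationError, match="failed"):
            ipsi.bootstrap_ci(boom, toy_panel, B=10, seed=0)


def test_max_weight_cap_counted(j2_law, spec05):
    panel = ipsi.sample_discrete_law(j2_law, 500, 9)
    nuis = ipsi.fit_nuisance(panel, treatment_formulas=J2_SAT_TREATMENT,
                             model_censoring=False)
    res = ipsi.wice_estimate(panel, spec05, nuis, J2_SAT_OUTCOME,
                             max_weight=1.01)
    assert res.weight_diagnostics.get("n_capped", 0) > 0
    assert res.weight_diagnostics["max"] <= 1.01
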