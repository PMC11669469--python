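import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from equity_audit import scenarios
from equity_audit.ordinal_regression import tests_frame as coefficient_frame
from equity_audit.ordinal_regression import (
    CoefficientTest,
    OrdinalProbit,
    build_design,
    neg_loglik,
    neg_loglik_grad,
    significant_interactions,
    wald_tests,
)
from equity_audit.synthetic_data import generate_cohort


def _random_instance(rng, n=300, p=3, J=4):
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=0.5, size=p)
    alpha = np.sort(rng.normal(scale=1.0, size=J - 1))
    alpha += 1e-3 * np.arange(J - 1)  # ensure strictly increasing
    y = np.digitize(X @ beta + rng.standard_normal(n), alpha)
    return X, y, beta, alpha


class TestDesign:
    def test_toy_design_is_hand_checkable(self, make_cohort):
        rows = [
            {"gender": "Male", "ethnicity": "White", "age": "30",
             "honos6_initial": "4", "uptake_CBTp": "taken_up"},
            {"gender": "Female", "ethnicity": "Black or Black British", "age": "20",
             "honos6_initial": "2", "uptake_CBTp": "taken_up"},
            {"gender": "Female", "ethnicity": "White", "age": "40",
             "honos6_initial": "1"},
            {"gender": "Male", "ethnicity": "White", "age": "20",
             "honos6_initial": "3", "uptake_Antipsychotic": "taken_up"},
        ]
        X = build_design(make_cohort(rows))
        assert list(X["initial_score"]) == [4.0, 2.0, 1.0, 3.0]
        assert list(X["CBTp"]) == [1.0, 1.0, 0.0, 0.0]
        assert list(X["Antipsychotic"]) == [0.0, 0.0, 0.0, 1.0]
        assert list(X["gender[Male]"]) == [1.0, 0.0, 0.0, 1.0]
        assert list(X["age_group[18-24]"]) == [0.0, 1.0, 0.0, 1.0]
        assert list(X["age_group[25-34]"]) == [1.0, 0.0, 0.0, 0.0]
        assert list(X["ethnicity[Black or Black British]"]) == [0.0, 1.0, 0.0, 0.0]
        # reference levels dropped
        assert "gender[Female]" not in X.columns
        assert "ethnicity[White]" not in X.columns
        assert "age_group[35-44]" not in X.columns

    def test_interaction_columns_are_exact_products(self):
        cohort = generate_cohort(scenarios.analysis_cohort(n=400, seed=31))
        wl = [("gender:Male", "CBTp"), ("gender:Male", "Antipsychotic"),
              ("age_group:18-24", "CBTp"), ("age_group:18-24", "Antipsychotic")]
        X = build_design(cohort, include_interactions=True, interaction_whitelist=wl)
        inter = [c for c in X.columns if " x " in c]
        assert len(inter) == 4
        for col in inter:
            parent_demo, parent_treat = col.split(" x ")
            np.testing.assert_array_equal(X[col], X[parent_demo] * X[parent_treat])

    def test_untreated_patient_has_zero_interactions(self, make_cohort):
        rows = [{"gender": "Male"}, {"gender": "Female"}] * 3
        X = build_design(make_cohort(rows), include_interactions=True)
        inter = [c for c in X.columns if " x " in c]
        # nobody took anything up: products are all zero, hence dropped
        assert inter == []

    def test_all_zero_column_dropped_with_warning(self, make_cohort, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="equity_audit"):
            X = build_design(make_cohort([{}, {"gender": "Male"}]))
        assert "CBTp" not in X.columns  # nobody took it up
        assert any("all zero" in r.message for r in caplog.records)


class TestLikelihood:
    def test_single_observation_even_split(self):
        # beta=0 and a single cutpoint at 0 halves the normal: -log(0.5)
        value = neg_loglik([0.0], [0.0], [[0.3]], [0])
        assert value == pytest.approx(-np.log(0.5))

    def test_matches_direct_evaluation(self, rng):
        X, y, beta, alpha = _random_instance(rng)
        a_ext = np.concatenate(([-np.inf], alpha, [np.inf]))
        eta = X @ beta
        direct = -np.log(norm.cdf(a_ext[y + 1] - eta) - norm.cdf(a_ext[y] - eta)).sum()
        assert neg_loglik(beta, alpha, X, y) == pytest.approx(direct, rel=1e-10)

    def test_gradient_matches_central_differences(self, rng):
        X, y, beta, alpha = _random_instance(rng, n=80)
        u = np.concatenate([beta, alpha])
        p = beta.size

        def f(v):
            return neg_loglik(v[:p], v[p:], X, y)

        num = np.empty(u.size)
        h = 1e-5
        for i in range(u.size):
            up, dn = u.copy(), u.copy()
            up[i] += h
            dn[i] -= h
            num[i] = (f(up) - f(dn)) / (2 * h)
        assert np.abs(neg_loglik_grad(beta, alpha, X, y) - num).max() < 1e-6

    def test_non_monotone_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            neg_loglik([0.0], [0.5, 0.2], [[1.0]], [0])


class TestFit:
    def test_intercept_only_reproduces_closed_form_cutpoints(self, rng):
        y = rng.integers(0, 4, 600)
        fit = OrdinalProbit().fit(np.empty((600, 0)), y)
        freq = np.bincount(y, minlength=4) / 600
        expected = ndtri(np.cumsum(freq)[:-1])
        np.testing.assert_allclose(fit.cutpoints_, expected, atol=1e-6)

    def test_agrees_with_statsmodels_on_random_instances(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        for _ in range(20):
            X, y, *_ = _random_instance(rng, n=300, p=3)
            if np.unique(y).size < 3:
                continue
            ours = OrdinalProbit().fit(X, y)
            res = OrderedModel(y, X, distr="probit").fit(method="bfgs", disp=0)
            np.testing.assert_allclose(ours.coef_, res.params[:3], atol=1e-4)
            th = np.asarray(OrderedModel(y, X, distr="probit")
                            .transform_threshold_params(res.params))[1:-1]
            np.testing.assert_allclose(ours.cutpoints_, th, atol=1e-4)

    def test_duplicating_rows_halves_variance(self, rng):
        X, y, *_ = _random_instance(rng, n=400)
        one = OrdinalProbit().fit(X, y)
        two = OrdinalProbit().fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(one.coef_, two.coef_, atol=1e-5)
        np.testing.assert_allclose(one.bse_[:3] / two.bse_[:3],
                                   np.sqrt(2.0) * np.ones(3), rtol=1e-3)

    def test_probabilities_sum_to_one_and_shift_monotonically(self, rng):
        X, y, *_ = _random_instance(rng, n=500)
        fit = OrdinalProbit().fit(X, y)
        grid = np.linspace(-2, 2, 9)[:, None] * np.array([[1.0, 0.0, 0.0]])
        proba = fit.predict_proba(grid)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-8)
        # increasing x*beta moves cumulative mass out of the low categories
        sign = np.sign(fit.coef_[0])
        cum = proba.cumsum(axis=1)[:, :-1] * sign
        assert (np.diff(cum, axis=0) <= 1e-10).all()

    def test_mle_beats_generating_parameters(self, rng):
        X, y, beta, alpha = _random_instance(rng, n=400)
        fit = OrdinalProbit().fit(X, y)
        assert -fit.loglik_ <= neg_loglik(beta, alpha, X, y) + 1e-6

    def test_recovers_generator_coefficients_at_scale(self):
        cohort = generate_cohort(scenarios.regression_recovery(n=5000, seed=32))
        X = build_design(cohort, include_interactions=True,
                         interaction_whitelist=[("gender:Male", "CBTp")])
        fit = OrdinalProbit().fit(X, cohort.outcome_change().astype(int))
        assert fit.converged_
        for j, col in enumerate(X.columns):
            true = scenarios.RECOVERY_TRUE_COEF.get(col, 0.0)
            assert abs(fit.coef_[j] - true) < 3.5 * fit.bse_[j], col

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            OrdinalProbit().fit(np.ones((10, 1)), np.zeros(10))


@pytest.fixture(scope="module")
def fitted():
    cohort = generate_cohort(scenarios.regression_recovery(n=2000, seed=33))
    X = build_design(cohort, include_interactions=True,
                     interaction_whitelist=[("gender:Male", "CBTp")])
    fit = OrdinalProbit().fit(X, cohort.outcome_change().astype(int))
    return fit, wald_tests(fit)


class TestWaldAndInteractions:

    def test_z_and_p_are_consistent(self, fitted):
        _, tests = fitted
        for t in tests:
            assert t.z == pytest.approx(t.estimate / t.std_error)
            assert t.p_value == pytest.approx(2 * ndtr(-abs(t.z)), rel=1e-9)
            assert t.significant == (t.p_value < 0.05)

    def test_cutpoints_not_reported(self, fitted):
        fit, tests = fitted
        assert len(tests) == fit.coef_.size

    def test_nonconverged_fit_refuses_tests(self, fitted):
        fit, _ = fitted
        import copy

        bad = copy.copy(fit)
        bad.converged_ = False
        with pytest.raises(ValueError, match="converge"):
            wald_tests(bad)

    def test_interaction_filtering_and_signs(self, fitted):
        _, tests = fitted
        sig = significant_interactions(tests, alpha=0.05)
        assert all(" x " in t.name for t in sig)
        no_inter = [t for t in tests if " x " not in t.name]
        assert significant_interactions(no_inter) == []

    def test_benjamini_hochberg_never_flags_more(self, fitted):
        _, tests = fitted
        plain = significant_interactions(tests, alpha=0.05, mtc="none")
        bh = significant_interactions(tests, alpha=0.05, mtc="benjamini_hochberg")
        assert {t.name for t in bh} <= {t.name for t in plain}

    def test_frame_has_confidence_bounds(self, fitted):
        _, tests = fitted
        frame = coefficient_frame(tests)
        assert (frame["ci_low"] <= frame["estimate"]).all()
        assert (frame["estimate"] <= frame["ci_high"]).all()
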