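"""The five linear comparators: exactness, equivalences, and selection behavior."""

import numpy as np
import pytest

from mycorun import BoxCoxTransform, fit_mlr, fit_olsr, fit_pcr, fit_plsr, fit_stepwise

IDENTITY = BoxCoxTransform(lmbda=1.0, offset=0.0)  # transform x -> x - 1, affine no-op for fits


@pytest.fixture()
def linear_data(rng):
    X = rng.uniform(0, 10, size=(300, 4))
    y = X @ [2.0, -3.0, 0.0, 1.0] + 1.0 + 60.0  # shifted well positive for the transform
    return X, y


class TestMLR:
    def test_exact_recovery_of_linear_truth(self, rng):
        X = rng.uniform(0, 5, size=(100, 2))
        y = 2 * X[:, 0] - 3 * X[:, 1] + 1 + 30  # shifted positive for the transform
        fit = fit_mlr(X, y, y_transform=IDENTITY)
        np.testing.assert_allclose(fit.coef, [2.0, -3.0], atol=1e-9)
        assert fit.intercept == pytest.approx(30.0, abs=1e-8)  # minus 1 from the transform
        np.testing.assert_allclose(fit.predict(X), y, atol=1e-8)

    def test_mlr_and_olsr_are_the_same_estimator(self, linear_data):
        X, y = linear_data
        a, b = fit_mlr(X, y, y_transform=IDENTITY), fit_olsr(X, y, y_transform=IDENTITY)
        assert (a.method, b.method) == ("mlr", "olsr")
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_rank_deficiency_rejected(self, rng):
        X = rng.uniform(0, 1, size=(50, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(ValueError, match="rank"):
            fit_mlr(X, X[:, 0] + 10, y_transform=IDENTITY)

    def test_pure_noise_has_no_out_of_sample_skill(self, rng):
        from mycorun import CVPlan, cross_validate
        from mycorun.baselines import baseline_factory

        X = rng.uniform(0, 1, size=(400, 4))
        y = rng.normal(10, 1, size=400)
        res = cross_validate(baseline_factory("mlr", y_transform=IDENTITY), X, y, CVPlan(k=8, repeats=2, seed=0))
        assert res.pooled_test.r2 <= 0.05


class TestStepwise:
    def test_single_active_input_is_usually_the_only_selection(self):
        exact = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, size=(500, 4))
            y = 5.0 * X[:, 1] + 10 + rng.normal(0, 0.3, 500)
            fit = fit_stepwise(X, y, y_transform=IDENTITY)
            assert 1 in fit.selected
            assert fit.coef[1] == pytest.approx(5.0, abs=0.3)
            exact += fit.selected == (1,)
        assert exact >= 7  # inactive inputs sneak past alpha=0.05 only occasionally

    def test_null_inputs_mostly_give_intercept_only(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, size=(200, 2))
            y = rng.normal(10, 1, size=200)
            fit = fit_stepwise(X, y, y_transform=IDENTITY)
            hits += fit.selected == ()
        assert hits >= 14  # per-feature false-entry rate alpha=0.05

    def test_alpha_enter_one_recovers_full_mlr(self, linear_data):
        X, y = linear_data
        full = fit_stepwise(X, y, y_transform=IDENTITY, alpha_enter=1.0, alpha_remove=1.0)
        mlr = fit_mlr(X, y, y_transform=IDENTITY)
        assert full.selected == (0, 1, 2, 3)
        np.testing.assert_allclose(full.predict(X), mlr.predict(X), atol=1e-8)

    def test_intercept_only_predicts_the_mean(self, rng):
        X = rng.uniform(0, 1, size=(100, 2))
        y = np.full(100, 7.0) + rng.normal(0, 1e-12, 100)
        fit = fit_stepwise(X, y, y_transform=IDENTITY)
        if fit.selected == ():
            np.testing.assert_allclose(fit.predict(X), y.mean(), atol=1e-6)


class TestPCR:
    def test_full_components_equal_mlr(self, linear_data):
        X, y = linear_data
        pcr = fit_pcr(X, y, n_components=4, y_transform=IDENTITY)
        mlr = fit_mlr(X, y, y_transform=IDENTITY)
        np.testing.assert_allclose(pcr.predict(X), mlr.predict(X), atol=1e-6)

    def test_survives_planted_collinearity(self, rng):
        X = rng.uniform(0, 1, size=(100, 3))
        X = np.column_stack([X, X[:, 2]])  # exact duplicate feature
        y = X[:, 0] + 10
        with pytest.raises(ValueError):
            fit_mlr(X, y, y_transform=IDENTITY)
        fit = fit_pcr(X, y, n_components=3, y_transform=IDENTITY)
        assert np.isfinite(fit.predict(X)).all()

    def test_component_count_capped_and_default_rule(self, linear_data):
        X, y = linear_data
        with pytest.raises(ValueError):
            fit_pcr(X, y, n_components=5, y_transform=IDENTITY)
        fit = fit_pcr(X, y, y_transform=IDENTITY)
        assert 1 <= fit.n_components <= 4


class TestPLSR:
    def test_univariate_matches_simple_regression(self, rng):
        x = rng.uniform(0, 10, size=(80, 1))
        y = 3.0 * x[:, 0] + 5 + rng.normal(0, 0.1, 80)
        pls = fit_plsr(x, y, n_components=1, y_transform=IDENTITY)
        mlr = fit_mlr(x, y, y_transform=IDENTITY)
        np.testing.assert_allclose(pls.predict(x), mlr.predict(x), atol=1e-8)

    def test_full_components_equal_mlr(self, linear_data):
        X, y = linear_data
        pls = fit_plsr(X, y, n_components=4, y_transform=IDENTITY)
        mlr = fit_mlr(X, y, y_transform=IDENTITY)
        np.testing.assert_allclose(pls.predict(X), mlr.predict(X), atol=1e-6)

    def test_zero_variance_response_rejected(self, rng):
        X = rng.uniform(0, 1, size=(30, 2))
        with pytest.raises(ValueError):
            fit_plsr(X, np.full(30, 4.0), y_transform=IDENTITY)
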