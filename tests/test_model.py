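"""Likelihood, priors, reparameterization and prior-predictive behavior."""

import math

import numpy as np
import pytest
from scipy import stats

from mitocast.data_model import PatientRecord, ValidationError
from mitocast.model import (
    CovariateTransform,
    ExponentialPrior,
    LogPosterior,
    ModelParameters,
    ModelVariant,
    NormalPrior,
    PriorConfig,
    from_noncentered,
    linear_predictor,
    log_likelihood_pointwise,
    log_prior,
    prior_predictive,
    to_noncentered,
)
from mitocast.synthetic_data import GeneratorConfig, simulate_dataset


def _params(**overrides):
    base = dict(
        alpha=0.0,
        beta=np.zeros(4),
        gamma=np.zeros(4),
        delta=0.0,
        epsilon=0.0,
        mu_beta=0.0,
        sigma_beta=1.0,
        mu_gamma=0.0,
        sigma_gamma=1.0,
    )
    base.update(overrides)
    return ModelParameters(**base)


@pytest.fixture(scope="module")
def transform(small_cohort):
    dataset, _ = small_cohort
    return CovariateTransform().fit(dataset)


@pytest.fixture
def record():
    return PatientRecord(
        site="stomach", size_mm=60, surface_mm2=3.0, biopsy_mitoses=4
    )


class TestLinearPredictor:
    def test_all_zero_coefficients_give_rate_one(self, transform, record):
        assert linear_predictor(_params(), record, transform) == pytest.approx(1.0)

    def test_intercept_only(self, transform, record):
        params = _params(alpha=math.log(5))
        assert linear_predictor(params, record, transform) == pytest.approx(5.0)

    def test_response_flip_changes_rate_by_coefficient_gap(self, transform):
        params = _params(alpha=0.5, delta=0.8, epsilon=-0.3)
        no_resp = PatientRecord(
            site="duodenum", size_mm=40, surface_mm2=2.0, biopsy_mitoses=6
        )
        resp = PatientRecord(
            site="duodenum", size_mm=40, surface_mm2=2.0, biopsy_mitoses=6,
            response=True,
        )
        m = math.log1p(6)
        ratio = linear_predictor(params, resp, transform) / linear_predictor(
            params, no_resp, transform
        )
        assert ratio == pytest.approx(math.exp((-0.3 - 0.8) * m), rel=1e-12)

    def test_rate_always_positive(self, transform, record):
        rng = np.random.default_rng(0)
        for _ in range(50):
            params = _params(
                alpha=rng.normal(scale=3),
                beta=rng.normal(scale=3, size=4),
                gamma=rng.normal(scale=3, size=4),
                delta=rng.normal(scale=3),
            )
            assert linear_predictor(params, record, transform) > 0

    def test_full_reduces_to_size_only_variant(self, transform, record):
        params = _params(alpha=0.7, beta=np.array([0.1, 0.2, 0.3, 0.4]))
        full = linear_predictor(params, record, transform, ModelVariant.FULL)
        size_only = linear_predictor(
            params, record, transform, ModelVariant.SIZE_NO_SURFACE
        )
        assert full == pytest.approx(size_only, rel=1e-12)

    def test_unfitted_transform_rejected(self, record):
        with pytest.raises(ValidationError):
            linear_predictor(_params(), record, CovariateTransform())


class TestLogLikelihood:
    def test_zero_count_at_unit_rate(self, small_cohort):
        dataset, _ = small_cohort
        # lambda = 1 for every record: log P(y=0) = -1
        transform = CovariateTransform().fit(dataset)
        ll = log_likelihood_pointwise(_params(), dataset, transform)
        y = np.array([r.specimen_mitoses for r in dataset])
        assert ll[y == 0] == pytest.approx(-1.0)

    def test_closed_form_at_rate_five(self, transform, small_cohort):
        dataset, _ = small_cohort
        ll = log_likelihood_pointwise(_params(alpha=math.log(5)), dataset, transform)
        y = np.array([r.specimen_mitoses for r in dataset])
        if np.any(y == 5):
            expected = 5 * math.log(5) - 5 - math.log(math.factorial(5))
            assert ll[y == 5] == pytest.approx(expected)

    def test_matches_exact_factorial_oracle(self, transform, small_cohort):
        dataset, _ = small_cohort
        params = _params(alpha=0.4, beta=np.full(4, 0.2), delta=0.5)
        ll = log_likelihood_pointwise(params, dataset, transform)
        for i, r in enumerate(dataset):
            y = r.specimen_mitoses
            if y > 20:
                continue
            lam = linear_predictor(params, r, transform)
            exact = y * math.log(lam) - lam - math.log(math.factorial(y))
            assert ll[i] == pytest.approx(exact, abs=1e-10)

    def test_missing_specimen_counts_named(self, transform):
        records = [
            PatientRecord(site="stomach", size_mm=50, surface_mm2=2,
                          biopsy_mitoses=1, specimen_mitoses=3),
            PatientRecord(site="stomach", size_mm=50, surface_mm2=2,
                          biopsy_mitoses=1),
        ]
        from mitocast.data_model import Dataset

        with pytest.raises(ValidationError, match=r"\[2\]"):
            log_likelihood_pointwise(_params(), Dataset(records), transform)


class TestLogPrior:
    def test_matches_scipy_closed_form(self):
        priors = PriorConfig()
        params = _params(
            alpha=1.0, beta=np.array([0.1, -0.2, 0.0, 0.3]),
            gamma=np.array([0.05, 0.0, -0.1, 0.2]),
            delta=0.4, epsilon=-0.1,
            mu_beta=0.1, sigma_beta=0.6, mu_gamma=0.0, sigma_gamma=0.3,
        )
        expected = (
            stats.norm.logpdf(1.0, 1.0, 1.0)
            + stats.norm.logpdf(0.1, 0.0, 0.5)
            + stats.expon.logpdf(0.6, scale=0.5)
            + stats.norm.logpdf(params.beta, 0.1, 0.6).sum()
            + stats.norm.logpdf(0.0, 0.0, 0.2)
            + stats.expon.logpdf(0.3, scale=0.2)
            + stats.norm.logpdf(params.gamma, 0.0, 0.3).sum()
            + stats.norm.logpdf(0.4, 0.0, 0.5)
            + stats.norm.logpdf(-0.1, 0.0, 0.5)
        )
        assert log_prior(params, priors) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_scale_out_of_support(self):
        params = _params(sigma_beta=0.0)
        assert log_prior(params, PriorConfig()) == -np.inf

    def test_doubling_exponential_rate_identity(self):
        sigma = 0.7
        base = PriorConfig(sigma_beta=ExponentialPrior(2.0))
        doubled = PriorConfig(sigma_beta=ExponentialPrior(4.0))
        params = _params(sigma_beta=sigma)
        diff = log_prior(params, doubled) - log_prior(params, base)
        assert diff == pytest.approx(math.log(2) - sigma * 2.0, rel=1e-12)


class TestNoncentered:
    def test_zero_deviate_recovers_hyper_mean(self):
        params = _params(mu_beta=0.42, sigma_beta=0.9)
        rebuilt = from_noncentered(params, {"z_beta": np.zeros(4)})
        np.testing.assert_allclose(rebuilt.beta, 0.42)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        params = _params(
            beta=rng.normal(size=4), gamma=rng.normal(size=4),
            mu_beta=rng.normal(), sigma_beta=rng.exponential() + 0.1,
            mu_gamma=rng.normal(), sigma_gamma=rng.exponential() + 0.1,
        )
        z = to_noncentered(params)
        rebuilt = from_noncentered(params, z)
        np.testing.assert_allclose(rebuilt.beta, params.beta, atol=1e-12)
        np.testing.assert_allclose(rebuilt.gamma, params.gamma, atol=1e-12)

    def test_parameterizations_define_same_posterior(self, small_cohort):
        # densities at matched points differ exactly by the affine Jacobian
        dataset, _ = small_cohort
        priors = PriorConfig()
        transform = CovariateTransform().fit(dataset)
        lp_c = LogPosterior(ModelVariant.FULL, dataset, priors, transform, "centered")
        lp_n = LogPosterior(
            ModelVariant.FULL, dataset, priors, transform, "noncentered"
        )
        rng = np.random.default_rng(2)
        for _ in range(100):
            params = _params(
                alpha=rng.normal(1, 0.5),
                beta=rng.normal(size=4) * 0.3,
                gamma=rng.normal(size=4) * 0.2,
                delta=rng.normal() * 0.3,
                epsilon=rng.normal() * 0.3,
                mu_beta=rng.normal() * 0.3,
                sigma_beta=rng.exponential(0.5) + 0.05,
                mu_gamma=rng.normal() * 0.2,
                sigma_gamma=rng.exponential(0.3) + 0.05,
            )
            jacobian = 4 * math.log(params.sigma_beta) + 4 * math.log(
                params.sigma_gamma
            )
            diff = lp_n.logp(lp_n.pack(params)) - lp_c.logp(lp_c.pack(params))
            assert diff == pytest.approx(jacobian, abs=1e-8)

    def test_gradients_match_finite_differences(self, small_cohort):
        dataset, _ = small_cohort
        transform = CovariateTransform().fit(dataset)
        rng = np.random.default_rng(3)
        for variant in ModelVariant:
            for par in ("centered", "noncentered"):
                lp = LogPosterior(variant, dataset, PriorConfig(), transform, par)
                theta = lp.initial_position(rng, scale=0.3)
                _, grad = lp.logp_grad(theta)
                eps = 1e-6
                for i in range(lp.dim):
                    up, down = theta.copy(), theta.copy()
                    up[i] += eps
                    down[i] -= eps
                    numeric = (lp.logp(up) - lp.logp(down)) / (2 * eps)
                    assert grad[i] == pytest.approx(numeric, rel=1e-4, abs=1e-5)


class TestMLEInvariant:
    def test_total_loglik_maximized_at_log_mean(self, small_cohort):
        dataset, _ = small_cohort
        transform = CovariateTransform().fit(dataset)
        y = np.array([r.specimen_mitoses for r in dataset])
        alpha_hat = math.log(y.mean())

        def total(alpha):
            return log_likelihood_pointwise(
                _params(alpha=alpha), dataset, transform
            ).sum()

        at_mle = total(alpha_hat)
        for shift in (-0.2, -0.05, 0.05, 0.2):
            assert total(alpha_hat + shift) < at_mle


class TestPriorPredictive:
    def test_default_priors_encode_field_knowledge(self):
        result = prior_predictive(PriorConfig(), n=1000, seed=0)
        assert result.share_below_5 > 0.5
        assert 0.0 < result.share_above_50 <= 0.10

    def test_degenerate_priors_collapse_to_point(self):
        priors = PriorConfig(
            alpha=NormalPrior(math.log(3), 0.0),
            delta=NormalPrior(0.0, 0.0),
            epsilon=NormalPrior(0.0, 0.0),
            mu_beta=NormalPrior(0.0, 0.0),
            sigma_beta=ExponentialPrior(float("inf")),
            mu_gamma=NormalPrior(0.0, 0.0),
            sigma_gamma=ExponentialPrior(float("inf")),
        )
        result = prior_predictive(priors, n=200, seed=1)
        np.testing.assert_allclose(result.lam, 3.0, rtol=1e-12)

    def test_reproducible_and_sized(self):
        a = prior_predictive(PriorConfig(), n=100, seed=9)
        b = prior_predictive(PriorConfig(), n=100, seed=9)
        np.testing.assert_array_equal(a.lam, b.lam)
        assert a.lam.size == 100
        with pytest.raises(ValidationError):
            prior_predictive(PriorConfig(), n=0, seed=0)
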