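"""Posterior predictive mixture, HDPI and retrodiction checks."""

import math

import numpy as np
import pytest
from scipy.stats import poisson

from mitocast.data_model import Dataset, PatientRecord, ValidationError
from mitocast.inference import PosteriorDraws
from mitocast.model import CovariateTransform, ModelVariant, PriorConfig
from mitocast.prediction import hdpi, posterior_predictive, retrodiction

RECORD = PatientRecord(site="stomach", size_mm=60, surface_mm2=3.0, biopsy_mitoses=4)


def _posterior_from_lambdas(lambdas, delta=0.5):
    """A hand-built posterior whose rate draws for RECORD are exactly `lambdas`.

    Uses the flat variant with zeroed surface/count coefficients so that
    lambda = exp(alpha); alpha draws are log(lambda).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    s = lambdas.size
    shape = (1, s)
    transform = CovariateTransform().fit(Dataset([RECORD]))
    return PosteriorDraws(
        variant=ModelVariant.FLAT_NO_SIZE,
        parameterization="centered",
        params={
            "alpha": np.log(lambdas).reshape(shape),
            "gamma": np.zeros((1, s, 4)),
            "delta": np.full(shape, delta),
            "epsilon": np.zeros(shape),
        },
        log_likelihood=np.zeros((1, s, 1)),
        energy=np.zeros(shape),
        divergent=np.zeros(shape, dtype=bool),
        accept_prob=np.ones(shape),
        step_size=np.array([0.1]),
        transform=transform,
        priors=PriorConfig(),
        seed=0,
    )


class TestPosteriorPredictive:
    def test_single_draw_recovers_poisson_pmf(self):
        post = _posterior_from_lambdas([1.0, 1.0], delta=0.0)
        record = PatientRecord(
            site="stomach", size_mm=60, surface_mm2=3.0, biopsy_mitoses=0
        )
        pred = posterior_predictive(post, record, support_max=60)
        expected = poisson.pmf(pred.support, 1.0)
        np.testing.assert_allclose(pred.pmf, expected / expected.sum(), atol=1e-12)

    def test_two_draw_equal_weight_mixture_oracle(self):
        post = _posterior_from_lambdas([2.0, 8.0], delta=0.0)
        record = PatientRecord(
            site="stomach", size_mm=60, surface_mm2=3.0, biopsy_mitoses=0
        )
        pred = posterior_predictive(post, record, support_max=200)
        mixture = 0.5 * poisson.pmf(pred.support, 2.0) + 0.5 * poisson.pmf(
            pred.support, 8.0
        )
        assert np.max(np.abs(pred.pmf - mixture / mixture.sum())) < 1e-12

    def test_pmf_normalized(self, fitted_posterior):
        pred = posterior_predictive(fitted_posterior, RECORD)
        assert pred.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pred.pmf >= 0)

    def test_mean_matches_rate_draws(self, fitted_posterior):
        # law of total expectation for a Poisson mixture
        pred = posterior_predictive(fitted_posterior, RECORD, support_max=400)
        assert pred.mean == pytest.approx(pred.lambda_samples.mean(), rel=1e-6)

    def test_truncation_warning_recorded(self):
        post = _posterior_from_lambdas([30.0, 40.0], delta=0.0)
        record = PatientRecord(
            site="stomach", size_mm=60, surface_mm2=3.0, biopsy_mitoses=0
        )
        pred = posterior_predictive(post, record, support_max=25)
        assert pred.warnings

    def test_response_arm_never_used_for_prediction(self, fitted_posterior):
        # a record flagged as responder gets the same forecast as without
        plain = posterior_predictive(fitted_posterior, RECORD)
        responder = PatientRecord(
            site="stomach", size_mm=60, surface_mm2=3.0, biopsy_mitoses=4,
            response=True,
        )
        flagged = posterior_predictive(fitted_posterior, responder)
        np.testing.assert_allclose(flagged.pmf, plain.pmf, atol=1e-12)

    def test_monotone_in_biopsy_count_when_delta_positive(self):
        post = _posterior_from_lambdas([2.0, 3.0], delta=0.5)
        means = []
        for mb in (0, 2, 6, 12):
            record = PatientRecord(
                site="stomach", size_mm=60, surface_mm2=3.0, biopsy_mitoses=mb
            )
            means.append(posterior_predictive(post, record, support_max=400).mean)
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_modal_band_holds_requested_mass(self, fitted_posterior):
        pred = posterior_predictive(fitted_posterior, RECORD)
        lo, hi = pred.modal_band
        assert 0 <= lo <= hi <= pred.support[-1]
        assert pred.pmf[lo : hi + 1].sum() >= 0.5
        # minimality: one fewer count cannot reach the mass
        if hi > lo:
            assert pred.pmf[lo + 1 : hi + 1].sum() < 0.5
            assert pred.pmf[lo:hi].sum() < 0.5


class TestHdpi:
    def test_uniform_grid_gives_minimal_window(self):
        lo, hi = hdpi(np.arange(1, 101), mass=0.89)
        assert hi - lo == 88  # 89 samples span 88 units
        assert 1 <= lo and hi <= 100

    def test_constant_samples_collapse(self):
        assert hdpi(np.full(50, 3.2)) == (3.2, 3.2)

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(13)
        samples = rng.standard_normal(100_000)
        lo, hi = hdpi(samples, 0.89)
        assert lo == pytest.approx(-1.598, abs=0.05)
        assert hi == pytest.approx(1.598, abs=0.05)

    def test_contains_requested_mass(self):
        rng = np.random.default_rng(14)
        samples = rng.exponential(size=5000)
        lo, hi = hdpi(samples, 0.89)
        inside = np.mean((samples >= lo) & (samples <= hi))
        assert inside >= 0.89

    @pytest.mark.parametrize("bad", [[], [1.0]])
    def test_too_few_samples_rejected(self, bad):
        with pytest.raises(ValidationError):
            hdpi(np.asarray(bad))

    @pytest.mark.parametrize("mass", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_mass_rejected(self, mass):
        with pytest.raises(ValidationError):
            hdpi(np.arange(10.0), mass=mass)


class TestRetrodiction:
    def test_single_record_report(self, fitted_posterior):
        dataset = Dataset(
            [
                PatientRecord(
                    site="stomach", size_mm=50, surface_mm2=2.5,
                    biopsy_mitoses=3, specimen_mitoses=6,
                )
            ]
        )
        report = retrodiction(fitted_posterior, dataset)
        assert len(report) == 1
        row = report.iloc[0]
        assert row["lambda_lo"] <= row["lambda_mean"] <= row["lambda_hi"]
        assert row["covered"] in (True, False)

    def test_coverage_reasonable_on_fitted_data(self, fitted_posterior, small_cohort):
        dataset, _ = small_cohort
        report = retrodiction(fitted_posterior, dataset)
        coverage = report["covered"].mean()
        # 89% predictive intervals on the training data: roughly calibrated
        assert 0.75 <= coverage <= 1.0
        assert set(report.columns) >= {
            "site", "size_mm", "surface_mm2", "lambda_mean", "covered",
        }
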