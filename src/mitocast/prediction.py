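"""Posterior predictive forecasting of the specimen mitotic count.

For a new tumor the posterior predictive distribution of the specimen count
is a Poisson mixture over posterior rate draws:

.. math::

    P(M^S = k) = \\frac{1}{S} \\sum_{s=1}^{S} \\mathrm{Pois}(k; \\lambda_s),

truncated at a configurable support bound and renormalized.  Predictions
always use the no-response coefficient arm: the response-arm coefficient is
estimated only to keep pre-treated training cases from polluting the
biopsy-count coefficient, and is deliberately not used for forecasting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .data_model import Dataset, PatientRecord, ValidationError
from .inference import PosteriorDraws, eta_draws

__all__ = [
    "PredictiveDistribution",
    "posterior_predictive",
    "lambda_draws",
    "hdpi",
    "retrodiction",
]


@dataclass
class PredictiveDistribution:
    """Probability mass over specimen counts 0..K for one new tumor."""

    support: np.ndarray  # integers 0..K
    pmf: np.ndarray
    lambda_samples: np.ndarray
    truncated_mass: float
    modal_band: tuple[int, int]
    modal_band_mass: float
    warnings: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def interval(self, mass: float = 0.89) -> tuple[int, int]:
        """Central predictive interval on counts via mixture quantiles."""
        cdf = self.cdf()
        lo_q, hi_q = (1 - mass) / 2, 1 - (1 - mass) / 2
        lo = int(self.support[np.searchsorted(cdf, lo_q)])
        hi = int(self.support[min(np.searchsorted(cdf, hi_q), len(cdf) - 1)])
        return lo, hi

    def summary(self) -> dict:
        lo, hi = self.interval()
        return {
            "mean": self.mean,
            "hdpi_lambda_89": list(hdpi(self.lambda_samples, 0.89)),
            "interval_counts_89": [lo, hi],
            "modal_band": list(self.modal_band),
            "modal_band_mass": self.modal_band_mass,
        }


def _smallest_band(pmf: np.ndarray, mass: float) -> tuple[int, int, float]:
    """Smallest set of consecutive counts whose total mass reaches ``mass``."""
    n = pmf.size
    cumulative = np.concatenate([[0.0], np.cumsum(pmf)])
    for width in range(1, n + 1):
        window = cumulative[width:] - cumulative[:-width]
        j = int(np.argmax(window))
        if window[j] >= mass:
            return j, j + width - 1, float(window[j])
    return 0, n - 1, float(pmf.sum())


def lambda_draws(
    draws: PosteriorDraws,
    record: PatientRecord,
    force_no_response: bool = True,
) -> np.ndarray:
    """Posterior draws of the specimen rate for one record."""
    transform = draws.transform
    d, s, m = transform.transform_record(record)
    flat = {name: draws.flat(name) for name in draws.params}
    eta = eta_draws(
        flat,
        draws.variant,
        np.array([record.site.index - 1]),
        np.array([d]),
        np.array([s]),
        np.array([m]),
        np.array([1.0 if record.response else 0.0]),
        force_no_response=force_no_response,
    )
    return np.exp(eta[:, 0])


def posterior_predictive(
    draws: PosteriorDraws,
    new_record: PatientRecord,
    support_max: int = 200,
    band_mass: float = 0.5,
) -> PredictiveDistribution:
    """Posterior predictive pmf of the specimen count for a new tumor.

    The response arm is forced off: forecasts always use the no-response
    biopsy-count coefficient.  If the truncation at ``support_max`` drops
    more than 1e-3 of the mixture mass a warning is recorded.
    """
    lam = lambda_draws(draws, new_record, force_no_response=True)
    support = np.arange(support_max + 1)
    pmf = poisson.pmf(support[:, None], lam[None, :]).mean(axis=1)
    total = float(pmf.sum())
    warnings = []
    if 1.0 - total > 1e-3:
        warnings.append(
            f"support_max={support_max} truncates {1 - total:.4f} of the "
            "predictive mass; increase it"
        )
    pmf = pmf / total
    lo, hi, got = _smallest_band(pmf, band_mass)
    return PredictiveDistribution(
        support=support,
        pmf=pmf,
        lambda_samples=lam,
        truncated_mass=1.0 - total,
        modal_band=(lo, hi),
        modal_band_mass=got,
        warnings=warnings,
    )


def hdpi(samples: np.ndarray, mass: float = 0.89) -> tuple[float, float]:
    """Highest-posterior-density interval: the shortest contiguous interval
    containing ``ceil(mass * n)`` of the sorted samples."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValidationError("hdpi needs at least 2 samples")
    if not 0.0 < mass < 1.0:
        raise ValidationError(f"mass must be in (0, 1), got {mass}")
    sorted_s = np.sort(samples)
    k = int(math.ceil(mass * sorted_s.size))
    k = min(max(k, 1), sorted_s.size)
    widths = sorted_s[k - 1 :] - sorted_s[: sorted_s.size - k + 1]
    j = int(np.argmin(widths))
    return float(sorted_s[j]), float(sorted_s[j + k - 1])


def retrodiction(
    draws: PosteriorDraws,
    dataset: Dataset,
    mass: float = 0.89,
) -> pd.DataFrame:
    """Posterior predictive check against the fitted data, one row per record.

    Reports the posterior mean rate, its HDPI, the predictive count interval
    and whether the observed specimen count falls inside it, plus the raw
    covariates needed for the usual rate-vs-observation plots (marker size
    proportional to biopsy surface and tumor size, one panel per site).
    """
    rows = []
    for i, record in enumerate(dataset):
        lam = lambda_draws(draws, record, force_no_response=False)
        lam_lo, lam_hi = hdpi(lam, mass)
        support_max = int(max(50, np.quantile(lam, 0.999) * 3))
        pred = posterior_predictive(draws, record, support_max=support_max)
        count_lo, count_hi = pred.interval(mass)
        observed = record.specimen_mitoses
        rows.append(
            {
                "record": i + 1,
                "site": record.site.label,
                "size_mm": record.size_mm,
                "surface_mm2": record.surface_mm2,
                "biopsy_mitoses": record.biopsy_mitoses,
                "response": record.response,
                "observed_specimen": observed,
                "lambda_mean": float(lam.mean()),
                "lambda_lo": lam_lo,
                "lambda_hi": lam_hi,
                "count_lo": count_lo,
                "count_hi": count_hi,
                "covered": (
                    bool(count_lo <= observed <= count_hi)
                    if observed is not None
                    else None
                ),
            }
        )
    return pd.DataFrame(rows).set_index("record")
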