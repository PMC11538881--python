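"""Synthetic GIST cohorts with the statistical structure the analysis assumes.

The real training cohort is private, so every test and demonstration runs on
data simulated here.  Two generator modes exist:

``model-faithful``
    Covariates (site, size, surface, response flag, biopsy count) are drawn
    from plausible clinical distributions, and the specimen count is Poisson
    with the rate given by the inferential model's linear predictor at known
    ("true") parameters.  This is the mode used for parameter-recovery
    validation: the fitted posterior can be checked against the generating
    parameters.

``dag-faithful``
    A latent per-tumor mitotic rate drives *both* counts: the specimen count
    is Poisson at the full rate, while the biopsy count is Poisson at the
    rate scaled by the examined surface over the 5 mm² reference area.  This
    reproduces the causal sampling-bias story (small biopsies under-sample
    mitoses) independently of the inferential model.

Defaults encode gastric predominance (60% stomach), log-normal sizes with a
50 mm median for gastric and 35 mm for other sites, biopsy surfaces on
(0.05, 5] mm², and a 15% rate of response to neoadjuvant therapy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data_model import Dataset, PatientRecord, Site, ValidationError
from .model import (
    CovariateTransform,
    ModelParameters,
    ModelVariant,
    PriorConfig,
    _eta_arrays,
    _dataset_arrays,
    replace_fit,
)

__all__ = [
    "GeneratorConfig",
    "SimulationTruth",
    "sample_covariates",
    "simulate_dataset",
    "sample_params_from_priors",
]

_LAMBDA_DRAW_CAP = 1e7

#: site order matches Site indices 1..4
_SITE_BY_INDEX = (
    Site.COLON_RECTUM,
    Site.DUODENUM,
    Site.SMALL_INTESTINE,
    Site.STOMACH,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator."""

    n: int = 100
    seed: int = 0
    mode: Literal["model-faithful", "dag-faithful"] = "model-faithful"
    #: P(site = colon-rectum, duodenum, small-intestine, stomach)
    site_probs: tuple[float, float, float, float] = (0.10, 0.10, 0.20, 0.60)
    #: median tumor size (mm) per site, same order as site_probs
    size_median_mm: tuple[float, float, float, float] = (35.0, 35.0, 35.0, 50.0)
    size_log_sd: float = 0.5
    #: biopsy surface ~ lo + Beta(a, b) * (hi - lo), mm²
    surface_beta: tuple[float, float] = (2.0, 2.0)
    surface_range_mm2: tuple[float, float] = (0.05, 5.0)
    response_prob: float = 0.15
    #: latent biopsy mitotic rate per 5 mm² ~ LogNormal(log(median), sd)
    biopsy_rate_median: float = 1.0
    biopsy_rate_log_sd: float = 1.0
    #: dag-faithful latent specimen rate ~ LogNormal(log(median), sd)
    latent_rate_median: float = 3.0
    latent_rate_log_sd: float = 1.0
    #: ground-truth parameters (model-faithful); None -> drawn from priors
    true_params: ModelParameters | None = None
    priors: PriorConfig = field(default_factory=PriorConfig)
    variant: ModelVariant = ModelVariant.FULL
    transform: CovariateTransform | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        probs = np.asarray(self.site_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("site_probs must be 4 nonnegative values summing to 1")
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValidationError("response_prob must be in [0, 1]")
        if self.mode not in ("model-faithful", "dag-faithful"):
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated cohort."""

    mode: str
    lam: np.ndarray
    params: ModelParameters | None
    transform: CovariateTransform | None
    seed: int

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": int(self.seed),
            "lambda": [float(x) for x in self.lam],
            "params": self.params.to_dict() if self.params is not None else None,
            "transform": self.transform.to_dict() if self.transform is not None else None,
        }


def _draw_covariates(rng: np.random.Generator, n: int, config: GeneratorConfig):
    sites = rng.choice(4, size=n, p=np.asarray(config.site_probs, dtype=float))
    medians = np.asarray(config.size_median_mm)[sites]
    size_mm = np.exp(np.log(medians) + config.size_log_sd * rng.standard_normal(n))
    lo, hi = config.surface_range_mm2
    a, b = config.surface_beta
    surface = lo + rng.beta(a, b, size=n) * (hi - lo)
    response = rng.random(n) < config.response_prob
    return sites, size_mm, surface, response


def sample_covariates(
    rng: np.random.Generator, n: int, config: GeneratorConfig | None = None
) -> Dataset:
    """Draw biopsy-time covariates (no specimen count) as a Dataset.

    Used by prior-predictive simulation, which needs realistic covariate
    records but supplies its own parameters.
    """
    config = config or GeneratorConfig(n=n)
    sites, size_mm, surface, response = _draw_covariates(rng, n, config)
    biopsy_rate = np.exp(
        np.log(config.biopsy_rate_median)
        + config.biopsy_rate_log_sd * rng.standard_normal(n)
    )
    biopsy = rng.poisson(biopsy_rate * surface / 5.0)
    records = [
        PatientRecord(
            site=_SITE_BY_INDEX[sites[i]],
            size_mm=float(size_mm[i]),
            surface_mm2=float(surface[i]),
            biopsy_mitoses=int(biopsy[i]),
            response=bool(response[i]),
            pretreated=bool(response[i]),
        )
        for i in range(n)
    ]
    return Dataset(records=tuple(records), provenance="synthetic covariates")


def simulate_dataset(config: GeneratorConfig) -> tuple[Dataset, SimulationTruth]:
    """Generate a cohort plus its ground truth (per-record rate, parameters).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    if config.mode == "model-faithful":
        covariates = sample_covariates(rng, n, config)
        transform = config.transform or CovariateTransform()
        if not transform.is_fitted:
            transform = replace_fit(transform, covariates)
        params = config.true_params
        if params is None:
            params = config.priors.sample_params(rng, config.variant)
        d, s, m = transform.transform_dataset(covariates)
        L, R = _dataset_arrays(covariates)
        eta = _eta_arrays(params, L, d, s, m, R, config.variant)
        lam = np.exp(eta)
        specimen = rng.poisson(np.minimum(lam, _LAMBDA_DRAW_CAP))
        records = [
            PatientRecord(
                site=r.site,
                size_mm=r.size_mm,
                surface_mm2=r.surface_mm2,
                biopsy_mitoses=r.biopsy_mitoses,
                response=r.response,
                pretreated=r.pretreated,
                specimen_mitoses=int(specimen[i]),
            )
            for i, r in enumerate(covariates)
        ]
        truth = SimulationTruth(
            mode=config.mode, lam=lam, params=params, transform=transform,
            seed=config.seed,
        )
        return (
            Dataset(records=tuple(records), provenance="synthetic model-faithful"),
            truth,
        )

    # dag-faithful: one latent rate drives both counts; the biopsy count is
    # thinned by the examined surface over the 5 mm² reference area.
    sites, size_mm, surface, response = _draw_covariates(rng, n, config)
    lam = np.exp(
        np.log(config.latent_rate_median)
        + config.latent_rate_log_sd * rng.standard_normal(n)
    )
    specimen = rng.poisson(np.minimum(lam, _LAMBDA_DRAW_CAP))
    biopsy = rng.poisson(np.minimum(lam * surface / 5.0, _LAMBDA_DRAW_CAP))
    records = [
        PatientRecord(
            site=_SITE_BY_INDEX[sites[i]],
            size_mm=float(size_mm[i]),
            surface_mm2=float(surface[i]),
            biopsy_mitoses=int(biopsy[i]),
            response=bool(response[i]),
            pretreated=bool(response[i]),
            specimen_mitoses=int(specimen[i]),
        )
        for i in range(n)
    ]
    truth = SimulationTruth(
        mode=config.mode, lam=lam, params=None, transform=None, seed=config.seed
    )
    return (
        Dataset(records=tuple(records), provenance="synthetic dag-faithful"),
        truth,
    )


def sample_params_from_priors(
    priors: PriorConfig,
    seed: int | np.random.Generator = 0,
    variant: ModelVariant | str = ModelVariant.FULL,
) -> ModelParameters:
    """One joint draw of model parameters from the prior distributions."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return priors.sample_params(rng, variant)
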