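"""Shared fixtures: synthetic cohorts and one reusable posterior fit."""

import numpy as np
import pytest
from hypothesis import settings

from mitocast.inference import SamplerConfig, fit
from mitocast.model import ModelParameters, ModelVariant, PriorConfig
from mitocast.synthetic_data import GeneratorConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """n=60 model-faithful cohort with known ground truth."""
    dataset, truth = simulate_dataset(GeneratorConfig(n=60, seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def strong_effect_params():
    """Fixed generating parameters with clear size/surface/count effects."""
    return ModelParameters(
        alpha=1.5,
        beta=np.array([0.3, 0.35, 0.4, 0.45]),
        gamma=np.array([-0.5, -0.4, -0.45, -0.35]),
        delta=1.0,
        epsilon=-0.8,
        mu_beta=0.35,
        sigma_beta=0.1,
        mu_gamma=-0.4,
        sigma_gamma=0.1,
    )


@pytest.fixture(scope="session")
def fitted_posterior(small_cohort):
    """FULL-variant posterior on the small cohort, shared across tests."""
    dataset, _ = small_cohort
    return fit(
        ModelVariant.FULL,
        dataset,
        sampler_config=SamplerConfig(chains=4, warmup=400, draws=400, seed=3),
    )
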