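"""Shared fixtures: small synthetic datasets and reusable MCMC fits.

MCMC fits are expensive, so the fits used across test modules are built
once per session at reduced (but converging) sampler settings.
"""

from __future__ import annotations

import numpy as np
import pytest

from metapriors import (
    GeneratorConfig,
    HierarchicalEffectsModel,
    McmcSettings,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """6 areas x 15 records from the generative model (no covariate shift)."""
    data, truth = simulate_dataset(
        GeneratorConfig(area_sizes=6, records_per_area=15, B_true=0.0, seed=42)
    )
    return data, truth


@pytest.fixture(scope="session")
def fitted_model1(small_dataset):
    data, _ = small_dataset
    model = HierarchicalEffectsModel(data, variance_family="gamma")
    settings = McmcSettings(n_chains=3, n_burn_in=1_000, n_samples=6_000, seed=7)
    return model.fit(settings)


@pytest.fixture(scope="session")
def fitted_model2(small_dataset):
    data, _ = small_dataset
    model = HierarchicalEffectsModel(data, model="model2", variance_family="gamma")
    settings = McmcSettings(n_chains=3, n_burn_in=1_000, n_samples=6_000, seed=8)
    return model.fit(settings)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
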