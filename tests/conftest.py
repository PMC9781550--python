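"""Shared fixtures: small seeded synthetic datasets and reusable fits.

MCMC-backed fixtures are session-scoped so expensive posterior fits are
computed once and shared across tests.
"""

import logging

import pytest

from pgxdose import (
    GeneratorConfig,
    McmcConfig,
    apply_exclusions,
    build_design,
    fit_phenotype_factor_model,
    generate_dataset,
)

logging.getLogger("pgxdose").setLevel(logging.ERROR)

#: Reduced sampler settings for unit tests on small problems.
TEST_MCMC = McmcConfig(n_steps=600, n_burn=600, n_chains=2, thin=4)


@pytest.fixture(scope="session")
def small_dataset():
    """Mixed substrate/non-substrate dataset at default noise conditions."""
    cfg = GeneratorConfig(n_substances=6, seed=101, studies_min=2, studies_max=5)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    points, truth = small_dataset
    working, _ = apply_exclusions(points, drop_em_rows=True)
    return build_design(working), working, truth


@pytest.fixture(scope="session")
def factor_dataset():
    """Substrate-only dataset with a common slope, as the score-estimation
    stage assumes (non-substrates excluded); group means are then
    slope x activity score."""
    cfg = GeneratorConfig(
        n_substances=8,
        seed=202,
        prop_nonzero=1.0,
        slope_mean=25.0,
        slope_sd=0.0,
        studies_min=2,
        studies_max=5,
        n_min=10,
        n_max=200,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def factor_fit(factor_dataset):
    points, truth = factor_dataset
    working, _ = apply_exclusions(points, drop_em_rows=True)
    unpooled, _ = apply_exclusions(working, drop_pool_rm17=True)
    g = fit_phenotype_factor_model(
        unpooled, mcmc=McmcConfig(n_steps=1200, n_burn=1200, n_chains=3, thin=6, seed=7)
    )
    return g, truth
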