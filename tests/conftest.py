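"""Shared fixtures: small simulated cohorts and reference summary tables."""

import numpy as np
import pytest

import threecrit as tc


@pytest.fixture(scope="session")
def default_config() -> tc.TraitConfig:
    """The reference-calibrated trait configuration (59 rats)."""
    return tc.TraitConfig(seed=7)


@pytest.fixture(scope="session")
def cohort59(default_config):
    """One 59-rat cohort: (traits, criterion scores)."""
    traits = tc.sample_latent_traits(default_config)
    scores = tc.simulate_criterion_scores(traits, default_config)
    return traits, scores


@pytest.fixture(scope="session")
def big_cohort():
    """A 100k-rat cohort for Monte-Carlo checks of the correlation structure."""
    cfg = tc.TraitConfig(n_rats=100_000, seed=11)
    traits = tc.sample_latent_traits(cfg)
    return cfg, traits, tc.simulate_criterion_scores(traits, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
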