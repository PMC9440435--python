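"""Shared fixtures: small simulated experiments reused across test modules."""

import pytest

from wheatpheno.design import ExperimentDesign
from wheatpheno.synthetic import (
    DEFAULT_TRAITS,
    make_profiles,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_design():
    return ExperimentDesign(n_genotypes=4, n_replicates=5, n_soil_pots=2)


@pytest.fixture(scope="session")
def signal_dataset(small_design):
    """Four genotypes: one built tolerant, one built sensitive."""
    profiles = make_profiles(small_design, tolerant=(0,), sensitive=(3,))
    return simulate_experiment(small_design, profiles, seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset(small_design):
    """Same design with every noise source switched off."""
    zero_noise = {t: 0.0 for t in DEFAULT_TRAITS}
    profiles = make_profiles(
        small_design, tolerant=(0,), sensitive=(3,), noise_sd=zero_noise
    )
    return simulate_experiment(
        small_design, profiles, seed=11, harvest_noise_cv=0.0
    )
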