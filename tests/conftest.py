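import dataclasses

import pytest

from adtherm.simulate import (
    CohortConfig,
    Protocol,
    benign_tissue_template,
    reduce_to_lumped,
)


@pytest.fixture(scope="session")
def protocol():
    return Protocol()


@pytest.fixture(scope="session")
def benign_lumped(protocol):
    return reduce_to_lumped(benign_tissue_template(), protocol)


@pytest.fixture(scope="session")
def small_protocol():
    """3x3 grids keep feature-extraction tests fast."""
    return Protocol(grid_side=3)


def small_cohort_config(seed=0, **overrides):
    """10-mass toy cohort (pairs of masses in 5 dogs), 3x3 grids."""
    defaults = dict(
        n_dogs=5,
        masses_per_dog_probs=(0.0, 1.0, 0.0),
        malignancy_prevalence=0.4,
        exact_counts=True,
        exact_prevalence=True,
        protocol=Protocol(grid_side=3),
        rng_seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def noiseless(config: CohortConfig, **overrides) -> CohortConfig:
    """All random effects and measurement noise switched off."""
    return dataclasses.replace(
        config,
        pixel_noise_sd=0.0,
        dog_lambda_log_sd=0.0,
        dog_baseline_sd=0.0,
        mass_lambda_log_sd=0.0,
        mass_baseline_sd=0.0,
        delta_base_sd=0.0,
        lambda_ratio_log_sd=0.0,
        **overrides,
    )


@pytest.fixture()
def toy_cohort_config():
    return small_cohort_config()
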