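import numpy as np
import pytest

from contrastpop.synthetic_data import (GeneratorConfig, LearningTrajectory,
                                        ReadoutConfig, generate_dataset)


@pytest.fixture(scope="session")
def small_config():
    """A reduced training course: fast enough for unit tests, same structure."""
    return GeneratorConfig(n_channels=8, n_days=10, trials_per_contrast=25,
                           seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def learning_off_config():
    return GeneratorConfig(
        n_channels=8, n_days=10, trials_per_contrast=25,
        trajectory=LearningTrajectory(c50_step=0.0, exponent_growth=1.0),
        noise_corr_early=0.09, noise_corr_late=0.09,
        readout=ReadoutConfig(noise_early=1.5, noise_late=1.5),
        seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
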