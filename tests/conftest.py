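import numpy as np
import pandas as pd
import pytest

from liketolike import synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SyntheticConfig(
        n_presyn=12,
        n_neurons=400,
        n_candidates_per_presyn=60,
        feature_dim=32,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return synthetic.generate_population(small_config)


@pytest.fixture(scope="session")
def small_pairs(small_config, small_population):
    neurons, profiles = small_population
    pairs, truth = synthetic.generate_anatomy(neurons, profiles, small_config)
    return pairs, truth


@pytest.fixture(scope="session")
def default_pairs():
    """One default-size replicate shared by the model tests."""
    cfg = synthetic.SyntheticConfig(seed=5)
    neurons, profiles = synthetic.generate_population(cfg)
    pairs, truth = synthetic.generate_anatomy(neurons, profiles, cfg)
    return cfg, neurons, profiles, pairs, truth
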