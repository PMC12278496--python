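import numpy as np
import pytest
from hypothesis import settings

import optircell as oc

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic population (40 cells × 6 points), fixed seed."""
    return oc.sample_population(oc.SyntheticConfig(seed=123))


@pytest.fixture(scope="session")
def preprocessed_dataset(default_dataset):
    """Default population after derivative → truncate(1350–1780) → normalise."""
    return oc.preprocess_dataset(default_dataset, oc.PreprocessConfig())


@pytest.fixture()
def grid():
    return oc.SyntheticConfig().make_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
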