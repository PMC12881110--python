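import numpy as np
import pytest

from driftprime import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset at study-truth means (10 x 80 trials),
    shared across inference tests to keep the suite fast."""
    trials, truth = generate_dataset(GeneratorConfig(n_participants=10,
                                                     n_items=20, seed=7))
    return trials, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A shared Model 8 fit of the small dataset."""
    from driftprime import FitConfig, HierarchicalDDM
    trials, truth = small_dataset
    res = HierarchicalDDM(trials, "Model 8").fit(
        FitConfig(n_chains=2, n_iter=1400, seed=3))
    return res, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
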