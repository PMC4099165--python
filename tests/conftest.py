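import numpy as np
import pytest

from nirauth import GeneratorConfig, SpectralDataset, simulate_dataset


def make_dataset(n_pos=4, n_neg=3, p=5, seed=0):
    """Small arbitrary labelled dataset for plumbing tests."""
    rng = np.random.default_rng(seed)
    wn = 4000.0 + 10.0 * np.arange(p)
    X = rng.random((n_pos + n_neg, p))
    labels = np.array(["POS"] * n_pos + ["NEG"] * n_neg, dtype=object)
    return SpectralDataset(wn, X, labels)


@pytest.fixture
def tiny_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic cohort shared by slower integration tests."""
    config = GeneratorConfig(n_pos=90, n_neg=60, outlier_fraction=0.0, seed=5)
    dataset, truth = simulate_dataset(config)
    return config, dataset, truth
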