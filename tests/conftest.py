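import numpy as np
import pytest

from sir import features, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic observer shared by module tests (fixed seed)."""
    truth = synthetic.default_ground_truth(n_voxels=60, seed=42)
    return synthetic.simulate_dataset(truth, n_trials=300, seed=42)


@pytest.fixture(scope="session")
def true_basis(small_dataset):
    """Ground-truth templates wrapped as a feature basis (isolates stages
    downstream of NMF from factorization noise)."""
    truth = small_dataset.truth
    return features.BrainFeatureBasis(
        truth.templates_flat().copy(),
        truth.templates.shape[1:],
        truth.feature_labels(),
    )


@pytest.fixture(scope="session")
def true_coefs(small_dataset, true_basis):
    return features.feature_coefficients(small_dataset.trials.masks, true_basis)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
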