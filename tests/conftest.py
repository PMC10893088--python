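import numpy as np
import pytest

import hypermda as h


@pytest.fixture(scope="session")
def small_dataset():
    """Default-scale synthetic dataset shared by pipeline-level tests."""
    return h.make_dataset(seed=1)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Very small instance for fast training-loop tests."""
    return h.make_dataset(n_m=20, n_d=12, rank=2, density=0.2, noise_sd=0.1, seed=3)


@pytest.fixture
def tiny_config():
    """Down-scaled model configuration for fast unit tests of the pipeline."""
    return h.ModelConfig(
        embedding_dim=16, n_hypernodes=8, fnn_hidden=16,
        epochs=3, batch_size=64, n_folds=3, seed=0,
    )


@pytest.fixture(scope="session")
def assoc_8x5():
    rng = np.random.default_rng(42)
    values = (rng.random((8, 5)) < 0.4).astype(float)
    values[0, 0] = 1.0  # guarantee a non-degenerate profile
    return h.AssociationMatrix(
        values,
        [f"m{i}" for i in range(8)],
        [f"d{j}" for j in range(5)],
    )
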