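import numpy as np
import pytest

from promclust import synthetic


@pytest.fixture(scope="session")
def planted():
    """Reference planted-bicluster matrix (default study conditions)."""
    return synthetic.make_planted_matrix(synthetic.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def toy_genome():
    return synthetic.make_toy_genome(n_genes=16, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
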