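import numpy as np
import pytest

from coevotree.jtt import jtt_model


@pytest.fixture(scope="session")
def model():
    return jtt_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_distance_matrix(rng, ids):
    """Random symmetric hollow matrix with positive off-diagonal entries."""
    from skbio import DistanceMatrix
    n = len(ids)
    a = rng.uniform(0.1, 2.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return DistanceMatrix(a, ids=ids)
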