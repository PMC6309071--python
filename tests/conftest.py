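import numpy as np
import pytest

from chromonet import ContactMatrix, simulate_truth
from chromonet.alpha import OptimizationConfig
from chromonet.synthetic import _default_alpha_config


@pytest.fixture
def cm3() -> ContactMatrix:
    """The minimal worked example: c_01 = 2, c_12 = 4, c_02 = 0."""
    return ContactMatrix(values=np.array([[0, 2, 0], [2, 0, 4], [0, 4, 0]], float))


@pytest.fixture
def cm4_full() -> ContactMatrix:
    """4 beads, all off-diagonal contacts positive."""
    m = np.ones((4, 4)) * 2.0
    np.fill_diagonal(m, 0.0)
    return ContactMatrix(values=m)


def random_contact_matrix(n: int, seed: int, density: float = 1.0) -> ContactMatrix:
    """Random symmetric nonnegative matrix; optional random sparsity."""
    rng = np.random.default_rng(seed)
    m = rng.lognormal(mean=0.5, sigma=0.8, size=(n, n))
    if density < 1.0:
        keep = rng.random((n, n)) < density
        m = m * keep
    m = np.triu(m, k=1)
    m = m + m.T
    return ContactMatrix(values=m)


@pytest.fixture(scope="session")
def truth50():
    """Noise-free synthetic bundle shared across test modules."""
    return simulate_truth(n=50, noise_cv=0.0, zero_frac=0.3, seed=2)


@pytest.fixture(scope="session")
def fitted50(truth50):
    from chromonet import ClusteringStrengthModel

    cfg = _default_alpha_config(2)
    return ClusteringStrengthModel(truth50.cm, config=cfg).fit()


@pytest.fixture
def small_config() -> OptimizationConfig:
    return OptimizationConfig(
        max_triples=500, max_triangles=500, seed=0, backend="penalty"
    )
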