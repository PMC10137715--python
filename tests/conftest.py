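import numpy as np
import pytest

from fisherrao import Gaussian


@pytest.fixture(scope="session")
def example_pair():
    """Shared-covariance bivariate pair used in the worked examples:
    N((-1,0), S), N((6,3), S) with S = [[1.1, 0.9], [0.9, 1.1]]."""
    S = np.array([[1.1, 0.9], [0.9, 1.1]])
    return Gaussian([-1.0, 0.0], S), Gaussian([6.0, 3.0], S)


@pytest.fixture(scope="session")
def han_park_pair():
    """Han & Park's bivariate benchmark pair: N((0,0), diag(1, 0.1)) and
    N((1,1), diag(0.1, 1)); geodesic-shooting reference distance 3.1329."""
    return (
        Gaussian([0.0, 0.0], np.diag([1.0, 0.1])),
        Gaussian([1.0, 1.0], np.diag([0.1, 1.0])),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230413)


def random_gaussian(rng: np.random.Generator, d: int, scale: float = 1.0) -> Gaussian:
    """A well-conditioned random normal: mean ~ N(0, scale^2), covariance
    A A^T + 0.5 I for A with standard normal entries."""
    A = rng.standard_normal((d, d))
    return Gaussian(scale * rng.standard_normal(d), A @ A.T + 0.5 * np.eye(d))


@pytest.fixture
def make_gaussian():
    return random_gaussian


def random_spd(rng: np.random.Generator, n: int) -> np.ndarray:
    A = rng.standard_normal((n, n))
    return A @ A.T + 0.5 * np.eye(n)


@pytest.fixture
def make_spd():
    return random_spd
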