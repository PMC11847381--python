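import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fronteat import DMUTable

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(X, Y, groups=None) -> DMUTable:
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = X.shape
    return DMUTable(
        dmu_ids=[f"D{i:03d}" for i in range(n)],
        X=X, Y=Y,
        input_names=[f"x{j + 1}" for j in range(m)],
        output_names=[f"y{r + 1}" for r in range(Y.shape[1])],
        groups=groups,
    )


def random_table(rng, n=None, m=None, s=None) -> DMUTable:
    n = n or int(rng.integers(3, 51))
    m = m or int(rng.integers(1, 6))
    s = s or int(rng.integers(1, 3))
    X = rng.uniform(0.0, 10.0, size=(n, m))
    Y = rng.uniform(0.5, 10.0, size=(n, s))
    return make_table(X, Y)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def four_point_table():
    """1-input toy: (x, y) = (1,2), (2,4), (3,3), (4,6)."""
    return make_table([[1.0], [2.0], [3.0], [4.0]], [2.0, 4.0, 3.0, 6.0])
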