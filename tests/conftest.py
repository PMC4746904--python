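import numpy as np
import pytest

from jointgt import CovariateSet, ResponseVector, fit_null


@pytest.fixture
def rng():
    return np.random.default_rng(20160209)


@pytest.fixture
def toy_null():
    """Intercept-only null on y = (1,2,3,4)."""
    return fit_null(ResponseVector(np.array([1.0, 2.0, 3.0, 4.0])))


@pytest.fixture
def toy_sets():
    """The N=4, J=2 toy covariate matrix with a second 3-column set."""
    x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 1.0]])
    z = np.array(
        [[0.5, 2.0, 1.0], [1.5, 0.0, -1.0], [-0.5, 1.0, 0.0], [2.0, -1.0, 1.0]]
    )
    return CovariateSet("x", x), CovariateSet("z", z)


def random_instance(rng, n, j, confounders=0):
    """A random response/null/covariate-set triple."""
    conf = rng.normal(size=(n, confounders)) if confounders else None
    y = ResponseVector(rng.normal(size=n), confounders=conf)
    null = fit_null(y)
    xset = CovariateSet("x", rng.normal(size=(n, j)))
    return y, null, xset
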