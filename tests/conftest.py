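import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def assert_distribution(p, length=None, tol=1e-12):
    p = np.asarray(p)
    if length is not None:
        assert p.shape == (length,)
    assert np.all(p >= -tol)
    assert abs(p.sum() - 1.0) < tol
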