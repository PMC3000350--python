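import numpy as np
import pytest

from incmi import BinnedTrain


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)


def bernoulli_train(rng, n, p=0.16):
    return BinnedTrain((rng.random(n) < p).astype(np.int64))


@pytest.fixture
def independent_pair(rng):
    """Two independent Bernoulli trains, moderate rate."""
    return bernoulli_train(rng, 2**14), bernoulli_train(rng, 2**14)


@pytest.fixture
def copy_pair(rng):
    """x[n] = y[n-3] for an i.i.d. fair-bit y: a deterministic lag-3 copy."""
    yv = rng.integers(0, 2, 2**14)
    xv = np.concatenate([np.zeros(3, dtype=np.int64), yv[:-3]])
    return BinnedTrain(xv), BinnedTrain(yv)
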