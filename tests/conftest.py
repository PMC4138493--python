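import numpy as np
import pytest

from neurodeep.rbm import RBMParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_params(seed=0, n_visible=4, n_hidden=3, hidden_type="tanh", scale=0.3):
    """A small random RBM for enumeration-based checks."""
    r = np.random.default_rng(seed)
    return RBMParams(
        W=r.normal(0, scale, (n_hidden, n_visible)),
        a=r.normal(0, 0.2, n_visible),
        b=r.normal(0, 0.2, n_hidden),
        sigma=np.ones(n_visible),
        hidden_type=hidden_type,
    )


@pytest.fixture
def tiny_rbm():
    return tiny_params()
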