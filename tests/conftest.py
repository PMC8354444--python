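import numpy as np
import pytest

import mbmeta
from mbmeta.metalearn import initialize_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Small, dynamically tame circuit for fast exact checks."""
    rng = np.random.default_rng(7)
    p = initialize_parameters(rng, n_mbon=4, n_dan=4, n_fbn=8, n_kc=20)
    p.W_recur *= 0.3  # keep the rectified dynamics well away from blow-up
    return p


@pytest.fixture
def default_params():
    return initialize_parameters(np.random.default_rng(0))


@pytest.fixture
def tiny_opts():
    return mbmeta.ConditioningOptions(n_kc=20)
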