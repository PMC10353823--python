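import numpy as np
import pytest

from snapnet.network_model import NetworkState, Rates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(beta, k=0.5, gamma=1.0, loads=None, initial=0, q=0.5):
    """Small helper to build a valid NetworkState from a beta vector."""
    beta = np.asarray(beta, dtype=float)
    L = beta.size
    kmat = np.full((L, L), float(k))
    np.fill_diagonal(kmat, 1.0)  # unused
    if loads is None:
        loads = np.ones(L, dtype=int)
    return NetworkState(
        loads=np.asarray(loads, dtype=int),
        success_probs=np.full(L, float(q)),
        rates=Rates(kmat, beta, gamma),
        initial_state=initial,
    )


@pytest.fixture
def one_state():
    return make_state([10.0])


@pytest.fixture
def two_state():
    return make_state([2.0, 12.0])
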