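import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_wss(times, vectors, **kw):
    """Single-element WssSeries from a (n_times, 3) array."""
    from graftmech.metrics import WssSeries

    vectors = np.asarray(vectors, dtype=float)[:, np.newaxis, :]
    return WssSeries(np.array(["e0"]), np.asarray(times, float), vectors, **kw)
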