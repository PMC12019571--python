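import numpy as np
import pytest

import chromkin as ck


@pytest.fixture(scope="session")
def model_params():
    return ck.ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_relaxed():
    """A relaxed 120-bead copolymer shared across dynamics tests."""
    track = ck.make_prototype_track(120, 0.5, 12.0, seed=7)
    params = ck.ModelParams()
    dyn = ck.DynamicsParams()
    state = ck.init_conformation(track, params, np.random.default_rng(7))
    state, _ = ck.relax(state, params, dyn, max_steps=6000, block_steps=2000, seed=7)
    return track, state, params, dyn
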