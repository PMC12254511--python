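import numpy as np
import pytest

import synconnect as sc


@pytest.fixture(scope="session")
def default_kernel():
    return sc.calibrate_kernel()


@pytest.fixture(scope="session")
def small_hyper_traceset():
    """One small hyperconnected field, reused across tests."""
    cfg = sc.make_config("hyperconnected", seed=11, n_neurons=10, duration=60.0)
    return sc.simulate_traceset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
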