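import numpy as np
import pytest

import dyncomm as dc


@pytest.fixture(scope="session")
def default_scenario():
    """One draw of the standard planted scenario, shared across tests."""
    cfg = dc.ScenarioConfig(seed=11)
    net, truth, meta = dc.generate_multilayer(cfg)
    return cfg, net, truth, meta


@pytest.fixture(scope="session")
def suppressed_scenario():
    cfg = dc.ScenarioConfig(seed=11, suppressed=True)
    net, truth, meta = dc.generate_multilayer(cfg)
    return cfg, net, truth, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_multilayer(rng, n, layers, density=1.0):
    """Small random symmetric multilayer network for oracle checks."""
    A = np.zeros((n, n, layers))
    iu = np.triu_indices(n, k=1)
    for l in range(layers):
        w = rng.uniform(0.05, 1.0, size=len(iu[0]))
        if density < 1.0:
            w *= rng.random(len(w)) < density
        M = np.zeros((n, n))
        M[iu] = w
        A[:, :, l] = M + M.T
    return dc.MultilayerNetwork(A)
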