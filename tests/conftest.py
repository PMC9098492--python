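import numpy as np
import pytest

import vestcode as vc


@pytest.fixture(scope="session")
def naturalistic_300s():
    """One long naturalistic trace shared across tests (300 s, 40 deg/s SD)."""
    return vc.generate_naturalistic(vc.NaturalisticGenParams(duration=300.0, seed=11))


@pytest.fixture(scope="session")
def naturalistic_60s():
    return vc.generate_naturalistic(vc.NaturalisticGenParams(duration=60.0, seed=7))


@pytest.fixture()
def sinusoid_8hz():
    return vc.generate_sinusoid(8.0, 15.0, 10.0)


@pytest.fixture(scope="session")
def tc_params():
    return vc.NeuronModelParams.tc()


@pytest.fixture(scope="session")
def vn_params():
    return vc.NeuronModelParams.vn()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
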