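import numpy as np
import pytest

from colonypattern import ModelParams, build_lattice_1d, build_lattice_hex


@pytest.fixture(scope="session")
def chain400():
    return build_lattice_1d(400)


@pytest.fixture(scope="session")
def chain100():
    return build_lattice_1d(100)


@pytest.fixture(scope="session")
def hex9():
    return build_lattice_hex(9, 9)


@pytest.fixture(scope="session")
def hex41():
    return build_lattice_hex(41, 41)


@pytest.fixture
def base_params():
    """Base kinetics with the moderate-decay regime (delta_H = 0.1,
    H_c = 0.1) where the well-mixed system has a comfortable interior
    fixed point."""
    return ModelParams(delta_H=0.1, H_c=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
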