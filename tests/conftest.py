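import numpy as np
import pytest

from cortexval.network import BrnConfig, RecordingSpec, build_network
from cortexval.structural import MembraneParams, SynapseKernel


@pytest.fixture(scope="session")
def tiny_cfg() -> BrnConfig:
    """A small balanced network for mechanics tests (not a benchmark)."""
    return BrnConfig(
        Ne=400, Ni=100, connectivity={"p": 0.1}, J=6.3, g=5.0,
        membrane=MembraneParams(), syn=SynapseKernel(J=6.3, tau_syn=5.0, delay=1.5),
        theta=1.5, name="tiny",
    )


@pytest.fixture(scope="session")
def tiny_net(tiny_cfg):
    return build_network(tiny_cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
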