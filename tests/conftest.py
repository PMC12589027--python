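import numpy as np
import pytest

from critsnn import NeuronParams, NetworkState, ProtocolConfig, STDPParams
from critsnn import build_network, preset_stdp


@pytest.fixture
def nparams():
    return NeuronParams()


@pytest.fixture
def stdp():
    return preset_stdp("crt")


@pytest.fixture
def small_state(nparams):
    """A tiny deterministic network (3 exc + 2 inh)."""
    cfg = ProtocolConfig(n_exc=3, n_inh=2, noise_seed=42, init_seed=7)
    return build_network(cfg, nparams)


def make_state(n_exc=3, n_inh=2, noise_seed=42, init_seed=7, params=None):
    cfg = ProtocolConfig(n_exc=n_exc, n_inh=n_inh, noise_seed=noise_seed,
                         init_seed=init_seed)
    return build_network(cfg, params or NeuronParams())
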