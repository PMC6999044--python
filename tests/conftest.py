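import numpy as np
import pytest

import moonjelly as mj


@pytest.fixture(scope="session")
def neuron_params():
    return mj.NeuronParams()


@pytest.fixture(scope="session")
def syn_params():
    return mj.SynapseParams()


@pytest.fixture(scope="session")
def ap_run(neuron_params, syn_params):
    """One synaptically evoked action potential from rest (trace, spikes)."""
    return mj.integrate_neuron(None, [0.0], neuron_params, syn_params, T=100.0)


@pytest.fixture(scope="session")
def small_mnn():
    return mj.build_mnn(1500, seed=0)


@pytest.fixture()
def two_neuron_net():
    """Two perpendicular neurites crossing once (delay 0.9 ms)."""
    return mj.NerveNet.from_segments(
        [[0.0, 0.0], [0.1, 0.1]], [0.0, np.pi / 2], 0.5, pacemakers=[0, 1])
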