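import numpy as np
import pytest

from isnsim import (
    PerturbationProtocol,
    SimulationConfig,
    build_isn_pointnet,
    make_ball_and_stick,
)
from isnsim.protocols import calibrate_isn


@pytest.fixture(scope="session")
def small_net_config():
    """A scaled-down E/I network for fast engine-level tests."""
    return {"n_exc": 80, "n_inh": 20}


@pytest.fixture(scope="session")
def small_net(small_net_config):
    return build_isn_pointnet(small_net_config, seed=11)


@pytest.fixture(scope="session")
def ball_stick():
    return make_ball_and_stick(soma_diam=20.0, dend_len=500.0, dend_diam=2.0, n_comp=20)


@pytest.fixture(scope="session")
def calibrated_isn():
    """Full-size network calibrated into the inhibition-stabilized regime.

    Calibration is the prerequisite of the paradoxical-effect and
    halorhodopsin experiments, so it is shared across the acceptance
    tests that exercise them.
    """
    net, report, scale = calibrate_isn(seed=1)
    assert report.is_isn
    return net, report, scale
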