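import pytest

from retrogate import (
    HeartbeatModel,
    ProtocolSpec,
    default_phantom_spec,
    simulate_triggers,
    synthesize_mge,
)


@pytest.fixture
def small_protocol():
    """Protocol scaled down to a 32x32 matrix, 20 measurements."""
    return ProtocolSpec(matrix=(32, 32), n_measurements=20)


@pytest.fixture
def small_phantom():
    return default_phantom_spec(grid=(32, 32))


@pytest.fixture
def constant_train(small_protocol):
    """Constant 119 ms heartbeat covering the small protocol's acquisition."""
    model = HeartbeatModel(distribution="constant", rr_mean=119.0, seed=0)
    return simulate_triggers(model, small_protocol.duration + 3 * 119.0)


@pytest.fixture
def small_sim(small_phantom, small_protocol, constant_train):
    """Noiseless static small acquisition."""
    return synthesize_mge(small_phantom, small_protocol, constant_train)
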