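import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meanet.types import N_ELECTRODES, SpikeTrainSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_trains(spikes_by_electrode: dict[int, list[float]], duration: float = 10.0) -> SpikeTrainSet:
    """Build a SpikeTrainSet with spikes only on the given electrodes."""
    spikes = [np.empty(0) for _ in range(N_ELECTRODES)]
    for e, ts in spikes_by_electrode.items():
        spikes[e] = np.sort(np.asarray(ts, dtype=float))
    return SpikeTrainSet(spikes=spikes, duration=duration)


@pytest.fixture
def trains_factory():
    return make_trains


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
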