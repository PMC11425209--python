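import numpy as np
import pytest

from wgmdyn.config import KineticScheme, SensorConfig


@pytest.fixture
def sensor() -> SensorConfig:
    """Default operating point: 780 nm, 1 mW, S̄=0.36, δλ̄=0.1 pm, 50 Hz."""
    return SensorConfig()


@pytest.fixture
def scheme() -> KineticScheme:
    """Turnover-like scheme: 3.5±0.5 fm spikes, 0.5 fm noise."""
    return KineticScheme(
        amp_mean=3.5e-15,
        amp_sd=0.5e-15,
        event_rate=0.5,
        mean_duration=0.1,
        noise_sd=0.5e-15,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
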