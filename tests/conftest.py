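import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

FS = 1000.0


@pytest.fixture(scope="session")
def fs():
    return FS


def tone(freq_hz, duration_s=10.0, amplitude=1.0, fs=FS, phase=0.0):
    t = np.arange(0.0, duration_s, 1.0 / fs)
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
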