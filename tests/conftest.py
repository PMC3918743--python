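import numpy as np
import pytest

from polysorter.recording_io import ProbeGeometry, VoltageRecord
from polysorter.synthetic import SimUnit, generate_recording, make_probe


@pytest.fixture
def two_site_probe():
    return ProbeGeometry(positions=np.array([[0.0, 0.0], [0.0, 50.0]]))


@pytest.fixture
def linear8_probe():
    return make_probe("linear", 8, 65.0)


@pytest.fixture
def noise_record(linear8_probe):
    rng = np.random.default_rng(42)
    V = rng.normal(0.0, 10.0, (8, 5000))
    return VoltageRecord(V, 40.0, linear8_probe)


@pytest.fixture(scope="session")
def two_unit_recording():
    """30 s, 8-channel linear probe, two well-separated units + truth."""
    probe = make_probe("linear", 8, 65.0)
    units = [
        SimUnit(archetype="A", amplitude_uV=220.0, x_um=0.0, y_um=100.0,
                rate_hz=6.0),
        SimUnit(archetype="C", amplitude_uV=180.0, x_um=0.0, y_um=320.0,
                rate_hz=6.0),
    ]
    return generate_recording(probe, units, duration_s=30.0,
                              noise_sigma_uV=15.0, seed=3)
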