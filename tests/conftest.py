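import numpy as np
import pytest

from nirsbci.synth import ParticipantProfile, build_protocol, simulate_trial


def quiet_profile(**overrides) -> ParticipantProfile:
    """A profile with every stochastic component switched off."""
    defaults = dict(
        noise_amp_mayer=0.0,
        noise_amp_resp=0.0,
        noise_amp_cardiac=0.0,
        drift_slope=0.0,
        white_noise_sd=0.0,
        coupling_gain_sd=0.0,
        coupling_offset_sd=0.0,
    )
    defaults.update(overrides)
    return ParticipantProfile(**defaults)


@pytest.fixture(scope="session")
def default_protocol():
    return build_protocol(seed=123)


@pytest.fixture(scope="session")
def noisy_recording():
    """One default-noise trial used by preprocessing tests."""
    return simulate_trial(ParticipantProfile(), ("MA", "NC", "MS"), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
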