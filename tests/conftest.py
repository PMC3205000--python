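import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from knobsim.model import HHParameters, StimulusProtocol
from knobsim.regimes import get_preset, PRESET_NAMES


@pytest.fixture(scope="session")
def presets():
    return {name: get_preset(name) for name in PRESET_NAMES}


@pytest.fixture()
def default_params():
    return HHParameters()


@pytest.fixture()
def default_protocol():
    return StimulusProtocol()


@pytest.fixture()
def passive_params():
    """Leak-only membrane: both voltage-gated conductances switched off."""
    return HHParameters(gNa_max=0.0, gK_max=0.0)
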