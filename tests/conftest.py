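import pytest

from sct import CapillarySystem, FluidProperties


@pytest.fixture
def water():
    return FluidProperties.water()


@pytest.fixture
def system():
    return CapillarySystem.default()
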