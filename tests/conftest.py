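import pytest

from cornealwave import AIR_TO_STROMA, ConicSurface, OpticalZone


@pytest.fixture
def zone6():
    return OpticalZone(6.0)


@pytest.fixture
def constants():
    return AIR_TO_STROMA


@pytest.fixture
def presbyopia_preop():
    """Pre-operative cornea of the presbyopic custom-ablation protocol."""
    return ConicSurface(7.8, -0.2)
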