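import pytest

import memcrowd as mc


@pytest.fixture
def mscl_channel() -> mc.ChannelGeometry:
    """MscL-like channel: radius 2.4 nm closed, 3.5 nm open."""
    return mc.ChannelGeometry(2.4, 3.5)


@pytest.fixture
def mscl_mixture() -> mc.CrowderMixture:
    """Half-protein membrane: uniform 1 nm crowders at area fraction 0.5."""
    return mc.CrowderMixture.uniform(1.0, area_fraction=0.5)
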