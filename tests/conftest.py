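import numpy as np
import pytest
from hypothesis import settings

from vpquant import CapsidModel, InstrumentSpec, SampleSpec, VPDefinition, reference

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def vps():
    """Default five-VP set (VP4 has zero Trp -> invisible on FLR)."""
    return reference.default_vps()


@pytest.fixture
def vps_visible_vp4():
    """Variant with a small nonzero VP4 response so all five peaks appear.

    Trp conservation across the VP0 cleavage is kept: trp(VP0) = trp(VP2) +
    trp(VP4).
    """
    return reference.default_vps(trp={"VP4": 1.0, "VP2": 5.0, "VP0": 6.0})


@pytest.fixture
def capsid():
    return CapsidModel()


@pytest.fixture
def inst():
    return InstrumentSpec(seed=0)


@pytest.fixture
def quiet_inst():
    """Noise-free instrument for closed-form area checks."""
    return InstrumentSpec(noise_sd=0.0, seed=0)


@pytest.fixture
def sample():
    """A mixed empty/full sample resembling a purification intermediate."""
    return SampleSpec(capsid_conc=3.66e12, empty_fraction=0.343)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
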