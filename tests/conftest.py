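import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dualcut.lesion_classifier import AmpliconReference
from dualcut.synthetic_data import ReferenceSpec, simulate_reference

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def amplicon() -> AmpliconReference:
    """Small deterministic amplicon with cuts at 60/110."""
    return simulate_reference(ReferenceSpec(length=160, cut_a=60, cut_b=110), seed=11)


@pytest.fixture
def default_amplicon() -> AmpliconReference:
    """The generator's default layout (200 bp, cuts 80/140)."""
    return simulate_reference(ReferenceSpec(), seed=11)
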