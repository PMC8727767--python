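import numpy as np
import pytest

from sibskit.cohort import load_cohort
from sibskit.simulate import SimParams


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged 32-patient cohort table."""
    return load_cohort()


@pytest.fixture(scope="session")
def fast_params():
    """Generator configuration at a reduced sampling rate for quick tests."""
    return SimParams(fs=64.0, section_duration_s=60.0, seed=0)


@pytest.fixture(scope="session")
def default_params():
    """Full-scale generator configuration (256 Hz, 10-minute sections)."""
    return SimParams(seed=0)
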