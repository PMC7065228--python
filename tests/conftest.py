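import numpy as np
import pytest

from mamskit.design import DesignSpec, socrates_design


@pytest.fixture(scope="session")
def socrates2():
    """Two-stage SOCRATES-style design: 3 doses + placebo, 97/arm,
    sigma = 0.52, drop at negative interim effect, upscaling."""
    return socrates_design(n_stages=2)


@pytest.fixture(scope="session")
def socrates3():
    return socrates_design(n_stages=3)


@pytest.fixture(scope="session")
def unit_design():
    """Small analytically convenient design: sigma^2 = 1, equal allocation."""
    return DesignSpec(n_arms=2, n_stages=2, control_stage_sizes=(50, 100))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
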