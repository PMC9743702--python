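import numpy as np
import pytest

from ratchetscan import ScanParameters, fitting_layouts, solo_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    return ScanParameters(p_pawl=0.001, p_leakage=0.77, p_nmd=0.62)


@pytest.fixture(scope="session")
def solo():
    return solo_layout()


@pytest.fixture(scope="session")
def fit_layouts():
    """Solo plus the 25 Duo layouts at dATG positions +7..+31."""
    solo, duos = fitting_layouts()
    return solo, duos


@pytest.fixture(scope="session")
def out_of_frame_duos(fit_layouts):
    _, duos = fit_layouts
    return [d for d in duos if not d.sites[1].functional]
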