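import numpy as np
import pytest

from strokemismatch import load_fixture_cohort
from strokemismatch.core import AcquisitionParams, GeometryParams
from strokemismatch import synthetic as syn


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_geometry():
    """32-matrix sampling of a 22-cm FOV: coarse but fast unit-test grid."""
    return GeometryParams(220.0 / 32.0, 6.0, (32, 32, 8))


@pytest.fixture(scope="session")
def phantom(small_geometry):
    return syn.make_phantom(small_geometry, core_fraction=0.1, territory_ml=50.0)


@pytest.fixture(scope="session")
def noiseless_series(phantom, acq):
    return syn.simulate_dsc(phantom, acq, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def retro_records():
    return load_fixture_cohort("retrospective")


@pytest.fixture(scope="session")
def prosp_records():
    return load_fixture_cohort("prospective")
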