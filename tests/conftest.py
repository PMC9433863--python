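import numpy as np
import pytest

from pelvimarrow import synthetic_data as sd


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size default phantom (96^3 at 1.5 mm), generated once."""
    return sd.generate_phantom(sd.PhantomConfig())


@pytest.fixture(scope="session")
def small_phantom():
    """A coarse, quick phantom for I/O and plumbing tests."""
    cfg = sd.PhantomConfig(
        shape=(48, 48, 48),
        spacing=(3.0, 3.0, 3.0),
        body_radius_mm=66.0,
        ring_radial_mm=(40.0, 48.0),
        ring_z_mm=(24.0, 120.0),
        voi_radii_mm=(33.0, 33.0, 33.0),
        seed=7,
    )
    return sd.generate_phantom(cfg)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 41-patient cohort plus its blood series."""
    return sd.realize_table3_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
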