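import numpy as np
import pytest

from rvecv.maps_io import T1Map
from rvecv.phantom import PhantomSpec, render_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom, 3 px wall, no noise: the clean test bed."""
    spec = PhantomSpec(rv_wall_thickness_px=3.0, noise_sd=0.0, seed=11)
    native, post, truth, geometry = render_phantom(spec)
    return spec, native, post, truth, geometry


@pytest.fixture(scope="session")
def r1_phantom():
    """Same geometry rendered in the analytic r1_domain mode."""
    spec = PhantomSpec(
        rv_wall_thickness_px=3.0, noise_sd=0.0, seed=11,
        partial_volume_mode="r1_domain",
    )
    return spec, *render_phantom(spec)


def make_map(values, spacing=(1.0, 1.0), phase="native", **kw):
    values = np.asarray(values, dtype=float)
    return T1Map(values, spacing, phase, **kw)


@pytest.fixture
def constant_map():
    """16x16 map of 1000 ms at 1 mm spacing."""
    return make_map(np.full((16, 16), 1000.0))
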