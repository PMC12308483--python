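import numpy as np
import pytest

from madwt._types import PhantomSpec
from madwt.synth import generate_phantom


@pytest.fixture(scope="session")
def uniform_phantom():
    """9-slice annulus, endo 20 mm, wall 8 mm everywhere, 1 mm spacing."""
    spec = PhantomSpec(
        endo_radius=20.0,
        sector_thickness=np.full(16, 8.0),
        in_plane_spacing=1.0,
        grid_size=96,
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def stepped_phantom():
    """Stepped phantom with a known random design, 0.5 mm spacing."""
    rng = np.random.default_rng(42)
    design = rng.uniform(6.0, 12.0, 16)
    spec = PhantomSpec(
        endo_radius=20.0,
        sector_thickness=design,
        in_plane_spacing=0.5,
        grid_size=160,
        rv_insertion_angle=25.0,
    )
    return spec, generate_phantom(spec)
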