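import numpy as np
import pytest

from ivcfind.phantom import FilterSpec, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small positive phantom: 24 slices of 96x96 with a 10-slice filter."""
    spec = PhantomSpec(
        shape=(24, 96, 96), spacing_mm=(5.0, 1.0, 1.0), spine_radius_px=6.0,
        filter=FilterSpec(apex_slice=8, span_slices=10, max_ring_radius_px=14.0,
                          ring_thickness_px=3.0, n_struts=6, strut_thickness_px=1.5),
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def negative_phantom():
    spec = PhantomSpec(shape=(24, 96, 96), spacing_mm=(5.0, 1.0, 1.0),
                       spine_radius_px=6.0, filter=None, seed=12)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
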