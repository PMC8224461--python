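import numpy as np
import pytest

from elastowave import (
    default_pulse,
    make_displacement_field,
    oce_geometry,
    use_geometry,
)


@pytest.fixture(scope="session")
def small_oce_geom():
    """Reduced OCE grid (same line span, fewer depths) for fast unit tests."""
    return oce_geometry(n_lateral=101, n_depth=12)


@pytest.fixture(scope="session")
def small_use_geom():
    return use_geometry(n_lateral=64, n_depth=60)


@pytest.fixture(scope="session")
def oce_field_3ms(small_oce_geom):
    """Noise-free OCE-geometry wave field at 3 m/s."""
    return make_displacement_field(
        small_oce_geom, 3.0, default_pulse("OCE"), seed=0
    )


@pytest.fixture(scope="session")
def use_field_3ms(small_use_geom):
    return make_displacement_field(
        small_use_geom, 3.0, default_pulse("USE"), seed=0
    )
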