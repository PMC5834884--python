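import pytest

from synquant.geometry import Window3D
from synquant import synthgen


@pytest.fixture
def cube_window():
    """10×10×10 μm window used throughout the spatial tests."""
    return Window3D(extents=(10_000.0, 10_000.0, 10_000.0))


@pytest.fixture
def small_window():
    return Window3D(extents=(3_000.0, 3_000.0, 3_000.0))


@pytest.fixture
def csr_pattern(cube_window):
    return synthgen.simulate_csr_pattern(0.5, cube_window, seed=42)


@pytest.fixture
def hardcore_pattern(cube_window):
    return synthgen.simulate_hardcore_pattern(0.5, 250.0, cube_window, seed=7)


@pytest.fixture
def cap_mesh():
    """Spherical-cap SAS at the control AS working point (area 117,800 nm²,
    curvature 0.049)."""
    return synthgen.synthesize_sas_mesh(117_800.0, 0.049, resolution=800, seed=3)


@pytest.fixture
def flat_mesh():
    return synthgen.synthesize_sas_mesh(50_000.0, 0.0, resolution=400, seed=5)
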