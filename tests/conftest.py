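import numpy as np
import pytest

from ffdreg import ControlPointMesh, build_luts, generate_phantom, make_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_setup(rng):
    """32x32 blob phantom, spacing-8 lattice, random mesh and LUTs."""
    image = generate_phantom((32, 32), kind="blobs", seed=7)
    geometry = make_geometry(image.shape, 8)
    luts = build_luts(geometry, image)
    coeffs = rng.normal(0.0, 1.0, geometry.cp_counts + (2,))
    mesh = ControlPointMesh(geometry, coeffs)
    return image, geometry, luts, mesh
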