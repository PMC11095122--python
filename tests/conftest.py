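import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from slotsim import (  # noqa: E402
    OpticalConfig,
    PhantomPair,
    generate_boundary,
    make_phantom,
    simulate_sinogram,
    trace_contour,
)


@pytest.fixture(scope="session")
def circle_pair():
    """Centered circular boundary with a uniform interior disk."""
    from scipy.ndimage import binary_erosion, binary_fill_holes

    size = (128, 128)
    boundary = generate_boundary(seed=0, size=size, mean_radius=45,
                                 irregularity=0.0)
    interior = binary_fill_holes(boundary > 0)
    structure = np.where(binary_erosion(interior, np.ones((9, 9))), 100.0, 0.0)
    return PhantomPair(boundary, structure)


@pytest.fixture(scope="session")
def logo_pair_small():
    return make_phantom(seed=3, size=(128, 128), pattern="logo_like",
                        boundary_params=dict(mean_radius=48, irregularity=0.08))


@pytest.fixture(scope="session")
def circle_contour(circle_pair):
    return trace_contour(circle_pair.surface)


@pytest.fixture(scope="session")
def matched_sino_small(logo_pair_small):
    cfg = OpticalConfig(n_medium=1.4, n_sample=1.4, n_projections=90)
    return simulate_sinogram(logo_pair_small, cfg), cfg
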