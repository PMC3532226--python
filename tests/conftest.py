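import numpy as np
import pytest
from hypothesis import settings

import layerquant as lq

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ring_geometry():
    """Blastula phantom: concentric rings r=100/80 px centered on a 256 canvas."""
    return lq.make_phantom_geometry(
        "blastula", outer_radius=100.0, thickness=20.0, n_nodes=16, center=(128.0, 128.0)
    )


@pytest.fixture(scope="session")
def gastrula_geometry():
    return lq.make_phantom_geometry(
        "late_gastrula", outer_radius=100.0, thickness=20.0,
        invagination_depth=35.0, n_nodes=24, center=(128.0, 128.0),
    )


@pytest.fixture(scope="session")
def bump_phantom(ring_geometry):
    """Gaussian-bump expression painted on the ring phantom, seeded noise."""
    image, truth = lq.render_profile_image(
        ring_geometry, lq.gaussian_bump(0.25, 0.06), 256, 256,
        background_level=0.95, noise_sd=0.01, seed=17,
    )
    return image, truth


@pytest.fixture(scope="session")
def ring_decomposition_100(ring_geometry):
    """Exactly 100 segments around the ring phantom."""
    seg_len = 2 * np.pi * 100.0 / 100
    return lq.decompose_cell_layer(ring_geometry, segment_length=seg_len)


@pytest.fixture()
def flat_profile():
    """A simple 20-segment profile on a closed loop of length 200."""
    positions = np.arange(20) * 10.0 + 5.0
    values = np.linspace(0.1, 0.9, 20)
    return lq.ExpressionProfile(
        positions=positions,
        mean_r=values.copy(), mean_g=values.copy(), mean_b=values.copy(),
        mean_grey=values.copy(), total_length=200.0,
    )
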