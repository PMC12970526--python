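import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from guvchol.phantoms import (
    DecayPhantomSpec,
    GuvGeometry,
    SpectralPhantomSpec,
    simulate_spectral_stack,
)


@pytest.fixture
def small_geometry():
    """Compact ring for fast spectral tests."""
    return GuvGeometry(center=(64.0, 64.0), radius=35.0, ring_width=4.0, image_size=(128, 128))


@pytest.fixture
def noisy_spectral(small_geometry):
    spec = SpectralPhantomSpec(gp_true=-0.51, geometry=small_geometry, seed=11)
    stack, truth = simulate_spectral_stack(spec)
    return spec, stack, truth


@pytest.fixture
def biexp_spec():
    return DecayPhantomSpec(
        component_fractions=(0.6, 0.4), component_lifetimes=(2.0, 5.0), photon_budget=1e6
    )


def noise_free_stack(spec: SpectralPhantomSpec):
    """Stack holding the exact expected (Poisson-mean) counts."""
    from guvchol.phantoms import expected_spectral_cube
    from guvchol.spectral_gp import SpectralStack

    cube = expected_spectral_cube(spec)
    return SpectralStack(data=cube, channel_centers=np.asarray(spec.channel_centers))
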