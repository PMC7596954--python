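import numpy as np
import pytest

from sbmtools import PhantomSpec, generate_phantom, smooth_fwhm


@pytest.fixture(scope="session")
def small_phantom():
    """Small default-structure phantom shared across read-only tests."""
    spec = PhantomSpec(
        grid_shape=(12, 14, 12),
        n_subjects=80,
        n_sources=3,
        source_radius_vox=1.8,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def smoothed_default_phantom():
    """Default-size phantom with pipeline smoothing applied (for ICA tests)."""
    dataset, truth = generate_phantom(PhantomSpec(seed=7))
    return smooth_fwhm(dataset, 4.0), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
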