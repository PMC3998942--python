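import numpy as np
import pytest

from centrotrack.simulate import generate_movie, suite_spec


@pytest.fixture(scope="session")
def suite_movie_0():
    """First default-suite movie (diameter 24 px, 1 µm oscillations)."""
    spec = suite_spec(0, base_seed=0)
    movie, truth = generate_movie(spec)
    return spec, movie, truth


@pytest.fixture(scope="session")
def small_movie():
    """A fast, small synthetic movie for I/O and CLI tests."""
    spec = suite_spec(
        1,
        base_seed=7,
        n_frames=12,
        frame_shape=(130, 210),
        embryo_center=(105.0, 65.0),
        embryo_semi_axes=(97.0, 58.0),
        centrosome_diameter=14.0,
        posterior_ap_start=18.0,
        posterior_ap_drift=20.0,
        anterior_ap_start=-28.0,
        anterior_ap_drift=-8.0,
        posterior_osc_amp_um=0.8,
        anterior_osc_amp_um=0.3,
    )
    movie, truth = generate_movie(spec)
    return spec, movie, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
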