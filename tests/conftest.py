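import numpy as np
import pytest

from ommapol import photometry, synthgen
from ommapol.photometry import IntensitySeries

DEFAULT_THETAS = np.arange(0.0, 185.0, 5.0)


def make_series(sigma, a=100.0, b=300.0, thetas=DEFAULT_THETAS, coord=(0, 0),
                noise_sd=0.0, rng=None):
    """Noiseless (or noisy) eyeshine intensity series of known Sigma."""
    values = a + b * np.sin(2.0 * np.deg2rad(thetas - sigma)) ** 2
    if noise_sd > 0:
        values = np.clip(values + rng.normal(0, noise_sd, values.shape), 0, None)
    return IntensitySeries(coordinate=coord, thetas=thetas, values=values)


@pytest.fixture(scope="session")
def small_field():
    """8x8 copy-with-jitter field, fixed seed."""
    return synthgen.generate_sigma_field(
        8, 8, synthgen.AlignmentParams(p_align=0.7, jitter_sd=2.0, seed=3)
    )


@pytest.fixture(scope="session")
def noiseless_stack(small_field):
    return synthgen.render_eyeshine_stack(small_field, seed=0)


@pytest.fixture(scope="session")
def noiseless_series(small_field, noiseless_stack):
    grid = photometry.grid_from_stack(noiseless_stack, 6.0, 8, 8)
    return photometry.extract_intensity_series(noiseless_stack, grid)
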