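import numpy as np
import pytest

from ntcc.synthetic import DEFAULT_PRESETS, generate_cell, generate_cells


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_patch(rng):
    """A seeded 16x16 8-bit random image."""
    return rng.integers(0, 256, size=(16, 16)).astype(np.uint8)


@pytest.fixture(scope="session")
def clean_cells():
    """One noise-free synthetic cell per class preset."""
    return [generate_cell(p, seed=7, noise_sd=0.0) for p in DEFAULT_PRESETS]


@pytest.fixture(scope="session")
def small_cell_batch():
    """A small labeled batch (10 cells/class) at default noise."""
    return generate_cells(n_per_class=10, seed=11)
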