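import numpy as np
import pytest

from ms2ident.simulate import NoiseModel, simulate_library
from ms2ident.spectra import make_spectrum


@pytest.fixture(scope="session")
def clean_library():
    """A 20-compound noiseless library + matched queries (shared, read-only)."""
    return simulate_library(20, seed=11, noise_model=NoiseModel.none())


def random_spectrum(rng: np.random.Generator, n_peaks: int = None, mz_max: float = 400.0,
                    **meta):
    """A random normalized spectrum for property tests."""
    n = n_peaks or int(rng.integers(2, 12))
    mzs = rng.uniform(50.0, mz_max, size=n)
    intens = rng.uniform(1.0, 100.0, size=n)
    return make_spectrum(zip(mzs, intens), **meta)
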