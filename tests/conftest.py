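import numpy as np
import pytest

from ssralpha import (SimParams, generate_epochs, generate_montage,
                      detrend_taper, fft_complex)


@pytest.fixture(scope="session")
def montage32():
    return generate_montage(32, seed=1)


@pytest.fixture(scope="session")
def montage16():
    return generate_montage(16, seed=2)


@pytest.fixture(scope="session")
def small_epochs(montage32):
    """One fast default-parameter subject (fewer trials for speed)."""
    params = SimParams(n_trials_per_condition=12, seed=5)
    epochs, gt = generate_epochs(params, montage32)
    return epochs, gt


@pytest.fixture(scope="session")
def small_spectra(small_epochs):
    epochs, _ = small_epochs
    return fft_complex(detrend_taper(epochs), df=0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
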