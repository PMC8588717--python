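import numpy as np
import pytest

from ferrospec.spectra_io import SpectralDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """3 samples x 5 bands toy dataset."""
    wl = np.array([400.0, 500.0, 600.0, 700.0, 800.0])
    spectra = rng.uniform(0.1, 0.9, size=(3, 5))
    return SpectralDataset(
        sample_ids=["a", "b", "c"],
        wavelengths=wl,
        spectra=spectra,
        tics=np.array([20.0, 22.0, 24.0]),
        soil_type=np.array(["loessial", "loessial", "sandy"], dtype=object),
    )
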