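import numpy as np
import pytest

import spectrareg as sr


@pytest.fixture(scope="session")
def small_dataset():
    """60-sample synthetic campaign with default physics, cropped + MSC'd."""
    spectra, targets, truth = sr.generate_dataset(sr.SyntheticConfig(n_samples=60, seed=42))
    cropped = sr.crop_bands(spectra)
    corrected, msc = sr.msc_fit_apply(cropped)
    return {"raw": spectra, "cropped": cropped, "corrected": corrected,
            "targets": targets, "truth": truth, "msc": msc}


@pytest.fixture(scope="session")
def noiseless_config():
    """Generator settings with scatter but no additive noise."""
    return sr.SyntheticConfig(n_samples=40, noise_sd=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
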