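import numpy as np
import pytest

from gecibench import ImagingConfig, generate_tuned_population, kinetics_preset


@pytest.fixture(scope="session")
def jrgeco_v1():
    return kinetics_preset("jRGECO1a", "v1")


@pytest.fixture(scope="session")
def jrgeco_nmj():
    return kinetics_preset("jRGECO1a", "nmj")


@pytest.fixture(scope="session")
def quiet_cfg():
    """Noiseless imaging configuration for exact-recovery checks."""
    return ImagingConfig(fs=15.0, noise_sd=0.0, neuropil_amp=0.0, r_true=0.7, seed=7)


@pytest.fixture(scope="session")
def small_population(jrgeco_v1):
    """Six fully responsive, moderately noisy cells (shared across tests)."""
    cfg = ImagingConfig(fs=15.0, noise_sd=0.02, neuropil_amp=0.05, r_true=0.7, seed=11)
    return generate_tuned_population(6, 1.0, jrgeco_v1, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
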