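import numpy as np
import pytest

import spikephase as sp

FS = 44000.0
BAND = (300.0, 6000.0)


@pytest.fixture(scope="session")
def nlp_filter():
    return sp.design_filter(sp.FilterSpec("NLP", "butterworth", 4, BAND, FS))


@pytest.fixture(scope="session")
def zp_filter():
    return sp.design_filter(sp.FilterSpec("ZP", "butterworth", 4, BAND, FS))


@pytest.fixture(scope="session")
def lp_filter():
    return sp.design_filter(sp.FilterSpec("LP", "fir_hamming", 20, BAND, FS))


@pytest.fixture(scope="session")
def template_04():
    return sp.make_template(0.4, FS)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation shared by distortion tests."""
    config = sp.SimulationConfig(
        rate=5.0, duration=4.0, width_hh_ms=0.4, target_snr=1e12, fs=FS, seed=3
    )
    return sp.assemble_signal(config)


@pytest.fixture(scope="session")
def noisy_sim():
    config = sp.SimulationConfig(
        rate=10.0, duration=20.0, width_hh_ms=0.4, target_snr=2.7, fs=FS, seed=7
    )
    return sp.assemble_signal(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
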