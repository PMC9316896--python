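import numpy as np
import pytest

from rcvkit import synthetic as syn


@pytest.fixture(scope="session")
def signature():
    return syn.default_signature()


@pytest.fixture(scope="session")
def instrument():
    return syn.InstrumentProfile()


@pytest.fixture(scope="session")
def quiet_instrument():
    """No noise, no baseline: spectra are the pure signature."""
    return syn.InstrumentProfile(noise_sd_per_scan=0.0, baseline_shift_sd=0.0)


@pytest.fixture(scope="session")
def narrow_instrument():
    """Small grid around the strong band; keeps Monte-Carlo loops cheap."""
    return syn.InstrumentProfile(wavenumber_min=1150.0, wavenumber_max=1310.0)


@pytest.fixture(scope="session")
def hand_coupon():
    """Default hand-deposition coupon at the visual limit."""
    return syn.generate_coupon(0.6, syn.DepositionProfile(), seed=7)


@pytest.fixture(scope="session")
def grid_coupon():
    """Printer-style uniform grid coupon at the visual limit."""
    return syn.generate_coupon(0.6, syn.DepositionProfile(inhomogeneity=0.0), seed=7)
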