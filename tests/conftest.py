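"""Shared fixtures: spectra and small scenes are expensive enough to cache
per session; Monte Carlo photon counts in unit tests are kept small and the
seeds fixed so every run is reproducible."""
from __future__ import annotations

import numpy as np
import pytest

from dbtdose import mc_transport as mc
from dbtdose import spectrum as sp


@pytest.fixture(scope="session")
def spectrum28():
    return sp.generate_spectrum(28)


@pytest.fixture(scope="session")
def spectrum25():
    return sp.generate_spectrum(25)


@pytest.fixture(scope="session")
def spectrum34():
    return sp.generate_spectrum(34)


@pytest.fixture(scope="session")
def mono20():
    """Nearly monoenergetic spectrum: all fluence in the 20.0-20.25 keV bin."""
    edges = 1.0 + 0.25 * np.arange(97)  # up to 25 keV
    fluence = np.zeros(96)
    fluence[int((20.0 - 1.0) / 0.25)] = 1.0
    return sp.EnergySpectrum(25.0, edges, fluence)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scene4(spectrum28):
    return mc.Scene(spectrum28, phantom=mc.PhantomStack(4.0))


@pytest.fixture
def scene2(spectrum25):
    return mc.Scene(spectrum25, phantom=mc.PhantomStack(2.0))
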