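import numpy as np
import pytest

from srpsim import (
    DMSO,
    ExcitationParams,
    FocalVolume,
    PhantomTruth,
    ProbeGeometry,
    cell_phantom_maps,
    make_phantom_stack,
    make_reference_spectra,
)
from srpsim.synthetic import default_ch_bands


@pytest.fixture
def excitation():
    return ExcitationParams()


@pytest.fixture
def focal():
    return FocalVolume()


@pytest.fixture
def dmso():
    return DMSO


@pytest.fixture
def probe():
    return ProbeGeometry()


@pytest.fixture
def small_optics():
    """Grid kwargs sized for fast unit tests (not production accuracy)."""
    return dict(n_grid=128, extent=10e-6, pad_factor=4, n_z=24)


@pytest.fixture
def wavenumbers():
    return np.arange(2790.0, 3031.0, 2.0)


@pytest.fixture
def references(wavenumbers):
    return make_reference_spectra(default_ch_bands(), wavenumbers)


@pytest.fixture
def phantom(references):
    maps = cell_phantom_maps(16, 16, tuple(references.names), seed=11)
    truth = PhantomTruth(maps, list(references.names), seed=11)
    return truth, make_phantom_stack(truth, references)
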