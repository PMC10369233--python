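"""Shared fixtures: model libraries, calibrations and small scenes."""

import numpy as np
import pytest

from srsfa.pipeline import DEFAULT_COMPONENTS
from srsfa.spectra import Spectrum, WavenumberAxis, fit_chain_length_calibration
from srsfa.synthetic import SceneSpec, make_gcms_profile, make_reference_spectra, make_scene


@pytest.fixture(scope="session")
def library():
    """Raw (unnormalized) eight-component model reference library."""
    return make_reference_spectra(DEFAULT_COMPONENTS)


@pytest.fixture(scope="session")
def norm_library(library):
    return library.normalized()


@pytest.fixture(scope="session")
def standards_library():
    """Pure saturated standards C6:0-C20:0 (the calibration series)."""
    return make_reference_spectra([f"C{n}:0" for n in range(6, 21, 2)])


@pytest.fixture(scope="session")
def calibration(standards_library):
    """Noiseless chain-length calibration from the standards series."""
    return fit_chain_length_calibration(
        [(c.chain_length, c.spectrum) for c in standards_library.saturated()]
    )


@pytest.fixture(scope="session")
def mixed_profile():
    return make_gcms_profile("mixed_producer")


@pytest.fixture(scope="session")
def small_scene(library, mixed_profile):
    """A small noisy mixed-producer scene with ground truth."""
    spec = SceneSpec(
        profile=mixed_profile, shape=(96, 96), n_cells=8, n_droplets=6, seed=5
    )
    return make_scene(spec, library)


@pytest.fixture(scope="session")
def noiseless_scene(library, mixed_profile):
    spec = SceneSpec(
        profile=mixed_profile, shape=(96, 96), n_cells=8, n_droplets=6,
        snr=1e9, seed=3,
    )
    return make_scene(spec, library)


@pytest.fixture()
def toy_axis():
    return WavenumberAxis(np.linspace(2800.0, 3050.0, 6))


@pytest.fixture()
def boxcar(toy_axis):
    return Spectrum(toy_axis, np.full(6, 3.0))
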