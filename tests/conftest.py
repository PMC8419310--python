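import numpy as np
import pytest

from neuromre.phantom import uniform_phantom_spec, make_phantom
from neuromre.waves import PAPER_FREQUENCIES_HZ, WaveField, simulate_plane_wave, simulate_wavefield

GRID2D = (60, 90)
SPACING3 = (0.8, 0.18, 0.18)


def make_plane_wavefield(c, phi, direction=(0, 1), grid=GRID2D,
                         freqs=PAPER_FREQUENCIES_HZ):
    """Analytic multifrequency plane-wave stack on one slice."""
    comps = np.zeros((len(freqs), 1, 1) + tuple(grid), dtype=complex)
    for i, f in enumerate(freqs):
        comps[i, 0, 0] = simulate_plane_wave(c, phi, f, direction, grid, SPACING3[1:])
    return WaveField(tuple(float(f) for f in freqs), comps, SPACING3)


def interior(shape3, margin):
    """Boolean mask of pixels at least `margin` px from the in-plane borders."""
    m = np.zeros(shape3, dtype=bool)
    m[:, margin:-margin, margin:-margin] = True
    return m


@pytest.fixture(scope="session")
def plane_wf_elastic():
    return make_plane_wavefield(3.0, 0.0)


@pytest.fixture(scope="session")
def plane_wf_visco():
    return make_plane_wavefield(3.0, 0.7)


@pytest.fixture(scope="session")
def solver_wf_elastic():
    """Homogeneous full-field elastic phantom pushed through the FDFD solver."""
    ph = make_phantom(uniform_phantom_spec(3.0, 0.0, grid_shape=(1,) + GRID2D))
    return simulate_wavefield(ph, refine=2), ph
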