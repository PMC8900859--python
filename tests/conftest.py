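import numpy as np
import pytest

import scatmap as sm


@pytest.fixture
def mini_waxs_geom():
    """Small wide-angle geometry covering q up to ~4 1/A at 1 A wavelength."""
    return sm.ExperimentGeometry(
        wavelength=1.0, det_distance=30.0, beam_center=(32.0, 32.0),
        pixel_pitch=0.5, det_shape=(64, 64), detector_name="waxs")


@pytest.fixture
def offcenter_geom():
    return sm.ExperimentGeometry(
        wavelength=1.0, det_distance=50.0, beam_center=(15.7, 16.3),
        pixel_pitch=0.5, det_shape=(32, 32), detector_name="det")


@pytest.fixture
def cellwall_materials():
    return sm.make_cellwall_materials()


def flat_profile(n=32, value=1.0, q_max=3.0):
    q = np.linspace(q_max / n, q_max, n)
    return sm.Profile1D(q, np.full(n, float(value)), np.zeros(n),
                        np.full(n, 10))
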