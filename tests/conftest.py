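import numpy as np
import pytest

from ethotrace.containers import ArenaGeometry
from ethotrace.posture import midlines_to_posture
from ethotrace.simulate import WaveParams, simulate_worm_midlines


@pytest.fixture(scope="session")
def wave_series():
    """Noiseless one-wavelength travelling wave, 200 frames, A=0.6, N=48."""
    params = WaveParams(amplitude=0.6, wavenumber=1.0, n_segments=48,
                        sigma=0.0, duration_s=10.0, frame_rate=20.0, seed=0)
    return simulate_worm_midlines(params)


@pytest.fixture(scope="session")
def wave_posture(wave_series):
    return midlines_to_posture(wave_series, n_points=49)


@pytest.fixture(scope="session")
def arena():
    """9 cm arena with the 4 cm aversion zone fully interior at the centre."""
    return ArenaGeometry(arena_radius_cm=9.0, zone_center_cm=(0.0, 0.0),
                         zone_radius_cm=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
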