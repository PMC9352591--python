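import numpy as np
import pytest

from fulm.config import default_two_vessel_segments
from fulm.grids import default_coarse_grid
from fulm.phantom import HemoModulation, StimulusProtocol, build_phantom, simulate_microbubbles


@pytest.fixture(scope="session")
def short_protocol():
    """A 3-pattern protocol with the standard 30/30/10 pattern."""
    return StimulusProtocol(rest_pre=30, stim=30, rest_post=10, n_patterns=3)


@pytest.fixture(scope="session")
def super_grid():
    return default_coarse_grid(16, 16).super_grid()


@pytest.fixture(scope="session")
def activated_truth(short_protocol):
    """Three-vessel phantom (activated arteriole + intraparenchymal branch,
    control venule) simulated over 3 patterns with moderate hyperemia."""
    phantom = build_phantom(default_two_vessel_segments(16, 16), seed=0)
    mod = HemoModulation(flux_gain=1.5, speed_gain=1.2, diameter_gain=1.2)
    return simulate_microbubbles(
        phantom, short_protocol, mod, duration=short_protocol.acq_t, seed=11, frame_rate=500
    )


@pytest.fixture(scope="session")
def null_truth(short_protocol):
    """Same phantom with all gains = 1 (no activation anywhere)."""
    phantom = build_phantom(default_two_vessel_segments(16, 16), seed=0)
    return simulate_microbubbles(
        phantom, short_protocol, HemoModulation(), duration=short_protocol.acq_t, seed=12, frame_rate=500
    )


def gaussian_spot_frame(shape, center_um, pitch_um, sigma_um, amp=1.0):
    """Render one Gaussian spot on a coarse grid (test helper)."""
    zc = (np.arange(shape[0]) + 0.5) * pitch_um[0]
    xc = (np.arange(shape[1]) + 0.5) * pitch_um[1]
    return amp * np.exp(
        -0.5 * ((zc[:, None] - center_um[0]) / sigma_um) ** 2
        - 0.5 * ((xc[None, :] - center_um[1]) / sigma_um) ** 2
    )
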