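import numpy as np
import pytest

from coanafor import Interferogram, TimeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid128():
    return TimeGrid(128, 5e-4)


def damped_fid(freqs, amps, relax, grid, phase_deg=0.0):
    """Closed-form sum of damped complex exponentials (test oracle helper)."""
    t = grid.times
    out = np.zeros(grid.n_points, complex)
    for f, a in zip(freqs, amps):
        out += a * np.exp((2j * np.pi * f - relax) * t)
    return out * np.exp(1j * np.deg2rad(phase_deg))


@pytest.fixture
def single_signal_fid(grid128):
    """Noiseless single damped exponential, full coverage."""
    data = damped_fid([150.0], [2.0 + 0.5j], 20.0, grid128)
    return Interferogram.from_prefix(data, grid128)
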