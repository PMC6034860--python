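import numpy as np
import pytest

from chromaquant.chromatogram_io import Chromatogram, Dialect
from chromaquant.peak_detection import gaussian


def make_chromatogram(time, intensity, sample_id="test"):
    return Chromatogram(
        sample_id=sample_id,
        time=np.asarray(time, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        dialect=Dialect.PLAIN_TSV,
    )


@pytest.fixture
def flat_chromatogram():
    t = np.arange(0.0, 10.0, 0.01)
    return make_chromatogram(t, np.full(t.size, 5.0))


def gaussian_chromatogram(
    centers,
    sigmas,
    amplitudes,
    region=(0.0, 20.0),
    dt=0.005,
    noise_sigma=0.0,
    baseline=0.0,
    seed=0,
):
    """Direct (non-package) construction of a multi-Gaussian chromatogram."""
    n = int(round((region[1] - region[0]) / dt)) + 1
    t = region[0] + dt * np.arange(n)
    y = np.full(n, float(baseline))
    for c, s, a in zip(np.atleast_1d(centers), np.atleast_1d(sigmas), np.atleast_1d(amplitudes)):
        y = y + gaussian(t, a, c, s)
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, n)
    return make_chromatogram(t, y)
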