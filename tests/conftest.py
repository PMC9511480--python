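import numpy as np
import pytest

from maldiscreen import simulate
from maldiscreen.io import Spectrum


@pytest.fixture
def small_config():
    """Fast spectrum config: reduced mass range and background, default noise."""
    return simulate.SpectrumSimConfig(
        n_background_peaks=10, mass_range=(2000.0, 10000.0), seed=7
    )


@pytest.fixture
def noiseless_config():
    """Single biomarker panel, no noise of any kind."""
    return simulate.SpectrumSimConfig(
        n_background_peaks=0,
        baseline_amplitude=0.0,
        multiplicative_cv=0.0,
        global_intensity_cv=0.0,
        additive_noise_sd=0.0,
        mz_jitter_sd=0.0,
        mass_range=(2000.0, 10000.0),
        seed=0,
    )


def gaussian_spectrum(center=5000.0, sigma=4.0, area=100.0, spacing=1.0,
                      lo=2000.0, hi=10000.0, baseline=None):
    grid = np.arange(lo, hi + spacing / 2, spacing)
    inten = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    if baseline is not None:
        inten = inten + baseline(grid)
    return Spectrum(grid, inten)
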