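import numpy as np
import pytest

from thzcryst.optics import AbsorptionSpectrum
from thzcryst.spectral_fit import quadratic
from thzcryst.synthetic_study import (
    DEFAULT_AMORPHOUS_BACKGROUND,
    PulseParams,
    default_reference_model,
)
from thzcryst.waveform_io import ScanMeta, Waveform


@pytest.fixture
def noiseless_pulse():
    return PulseParams(noise_std_au=0.0)


@pytest.fixture
def alpha_model():
    return default_reference_model("alpha")


@pytest.fixture
def beta_model():
    return default_reference_model("beta")


@pytest.fixture
def fit_grid():
    """Dense frequency axis covering the analysis band."""
    return np.linspace(0.3, 2.0, 851)


def make_spectrum(freq, alpha, **meta):
    return AbsorptionSpectrum(freq, alpha, (freq[0], freq[-1]), ScanMeta(**meta))


@pytest.fixture
def mixture_spectrum_factory(alpha_model, beta_model, fit_grid):
    """Build noiseless mixture spectra A·(α peaks) + B·(β peaks) + quadratic."""

    def _make(A, B, background=DEFAULT_AMORPHOUS_BACKGROUND, noise_std=0.0, rng=None):
        y = (
            A * alpha_model.peak_profile(fit_grid)
            + B * beta_model.peak_profile(fit_grid)
            + quadratic(background, fit_grid)
        )
        if noise_std > 0:
            y = y + (rng or np.random.default_rng(0)).normal(0.0, noise_std, len(fit_grid))
        return make_spectrum(fit_grid, y)

    return _make


@pytest.fixture
def simple_waveform():
    t = np.arange(0, 20, 0.1)
    u = (t - 10.0) / 0.5
    amp = -u * np.exp(-(u**2) / 2)
    return Waveform(t, amp, ScanMeta(sample_id="s0", thickness_mm=1.0))
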