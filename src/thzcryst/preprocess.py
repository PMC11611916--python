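"""Waveform conditioning: averaging, DC removal, Tukey windowing, FFT.

The chain mirrors standard THz-TDS practice: raw transients are averaged,
the detector DC offset is estimated from the quiet pre-pulse head of the
record and subtracted, a Tukey window suppresses truncation ringing, and the
record is zero-padded before a real-input Fourier transform.  The forward
transform is unscaled; the identical normalization is applied to sample and
reference scans so it cancels in the transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .waveform_io import ScanMeta, Waveform


@dataclass
class ComplexSpectrum:
    """One-sided complex spectrum of a (windowed, padded) waveform.

    ``freq_THz`` is the uniform rfft frequency axis starting at 0;
    ``field`` the complex spectral amplitudes.  The window parameter and pad
    length used are recorded so processing is reproducible from the object.
    """

    freq_THz: np.ndarray
    field: np.ndarray
    meta: ScanMeta
    tukey_alpha: float = 0.0
    pad_length: int = 0

    def __post_init__(self):
        if len(self.freq_THz) != self.pad_length // 2 + 1:
            raise ValueError("one-sided spectrum length must equal pad_length/2 + 1")
        if self.freq_THz[0] != 0.0:
            raise ValueError("frequency axis must start at 0")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.field)


def average_waveforms(waveforms) -> Waveform:
    """Pointwise arithmetic mean of repeated acquisitions of one scan.

    All inputs must share the time axis and sample id; the result's
    ``n_averages`` records how many raw records went in.
    """
    waveforms = list(waveforms)
    if not waveforms:
        raise ValueError("need at least one waveform to average")
    first = waveforms[0]
    for wf in waveforms[1:]:
        if not np.allclose(wf.time_ps, first.time_ps, rtol=0, atol=1e-9 * first.dt_ps):
            raise ValueError("cannot average waveforms with mismatched time axes")
        if wf.meta.sample_id != first.meta.sample_id:
            raise ValueError("cannot average waveforms from different samples")
    mean = np.mean([wf.amplitude_au for wf in waveforms], axis=0)
    return first.with_amplitude(mean, n_averages=len(waveforms))


def remove_dc(wf: Waveform, head_ps: float = 5.0) -> Waveform:
    """Subtract the mean amplitude over the first ``head_ps`` of the record.

    The head interval is half-open, [t0, t0 + head_ps), relative to the first
    sample; the generator guarantees this window precedes the THz transient,
    so it estimates the detector offset only.
    """
    if head_ps >= wf.span_ps:
        raise ValueError(
            f"DC head ({head_ps} ps) must be shorter than the record ({wf.span_ps:.3g} ps)"
        )
    mask = wf.time_ps < wf.time_ps[0] + head_ps
    offset = float(np.mean(wf.amplitude_au[mask]))
    return wf.with_amplitude(wf.amplitude_au - offset)


def apply_window(wf: Waveform, tukey_alpha: float = 0.1) -> Waveform:
    """Multiply by a Tukey window spanning the full record.

    ``tukey_alpha`` = 0 is the rectangular window (identity); 1 is a Hann
    window.  The default mild taper preserves nearly all pulse energy while
    suppressing edge discontinuities.
    """
    if not 0.0 <= tukey_alpha <= 1.0:
        raise ValueError("tukey_alpha must lie in [0, 1]")
    w = windows.tukey(len(wf.time_ps), alpha=tukey_alpha, sym=True)
    return wf.with_amplitude(wf.amplitude_au * w)


def to_spectrum(wf: Waveform, pad_factor: int = 4) -> ComplexSpectrum:
    """Zero-pad and Fourier-transform a real waveform.

    Pads to ``pad_factor`` times the next power of two at or above the record
    length, then takes the one-sided (rfft) transform.  The frequency axis in
    THz follows directly from the ps sampling interval (1/ps = THz).
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    n = len(wf.time_ps)
    pad_length = int(pad_factor) * int(2 ** np.ceil(np.log2(n)))
    field = np.fft.rfft(wf.amplitude_au, n=pad_length)
    freq = np.fft.rfftfreq(pad_length, d=wf.dt_ps)
    return ComplexSpectrum(freq, field, wf.meta, tukey_alpha=np.nan, pad_length=pad_length)


def preprocess_waveform(
    wf: Waveform,
    head_ps: float = 5.0,
    tukey_alpha: float = 0.1,
    pad_factor: int = 4,
) -> ComplexSpectrum:
    """Full conditioning chain: DC removal, Tukey window, padded transform."""
    windowed = apply_window(remove_dc(wf, head_ps=head_ps), tukey_alpha=tukey_alpha)
    spec = to_spectrum(windowed, pad_factor=pad_factor)
    spec.tukey_alpha = tukey_alpha
    return spec
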