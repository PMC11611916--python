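"""Optical-constant extraction from sample/reference spectrum pairs.

For a plano-parallel tablet of thickness d measured in transmission, the
complex transfer function T̃(ν) = Ẽ_sample/Ẽ_reference yields the refractive
index from the processed phase difference,

    n(ν) = 1 + c·Δφ(ν) / (2πν·d),

and the absorption coefficient after correcting the Fresnel interface loss,

    α(ν) = −(2/d)·ln( (n+1)²/(4n) · |T̃(ν)| ),

computed internally in SI units and reported in cm⁻¹.  Both are evaluated
strictly inside a declared analysis band: the phase formula is singular at
ν = 0 and the spectrum carries no usable dynamic range outside the pulse
bandwidth.

Phase processing: the wrapped phase of T̃ is unwrapped upward from the
lowest in-band frequency, negated so a delayed sample pulse has positive
Δφ, then shifted by the integer multiple of 2π nearest the intercept of a
linear fit over the band, so the extrapolated Δφ(ν) passes through the
origin.  This is the standard branch fix for transmission TDS and makes the
extraction insensitive to where unwrapping starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ComplexSpectrum, preprocess_waveform
from .waveform_io import ScanMeta, Waveform

#: Speed of light, m/s.
C_M_PER_S = 299_792_458.0

#: Default analysis band, THz.
DEFAULT_BAND_THZ = (0.3, 2.0)

#: Reference bins below this fraction of the peak reference magnitude are
#: considered outside the instrument's dynamic range.
DYNAMIC_RANGE_FLOOR = 1e-6


class DynamicRangeError(ValueError):
    """Reference spectrum too weak inside the requested band."""


@dataclass
class TransferFunction:
    """|T̃(ν)| and branch-corrected phase difference over the analysis band."""

    freq_THz: np.ndarray
    magnitude: np.ndarray
    delta_phi_rad: np.ndarray
    band_THz: tuple
    meta: ScanMeta = field(default_factory=ScanMeta)


@dataclass
class OpticalConstants:
    """n(ν) and α(ν) for one scan at known tablet thickness."""

    freq_THz: np.ndarray
    n: np.ndarray
    alpha_cm1: np.ndarray
    thickness_mm: float
    band_THz: tuple
    meta: ScanMeta = field(default_factory=ScanMeta)

    def absorption_spectrum(self) -> "AbsorptionSpectrum":
        return AbsorptionSpectrum(self.freq_THz, self.alpha_cm1, self.band_THz, self.meta)


@dataclass
class AbsorptionSpectrum:
    """α(ν) in cm⁻¹ restricted to the analysis band, with scan metadata."""

    freq_THz: np.ndarray
    alpha_cm1: np.ndarray
    band_THz: tuple
    meta: ScanMeta = field(default_factory=ScanMeta)

    def restrict(self, band_THz) -> "AbsorptionSpectrum":
        lo, hi = band_THz
        m = (self.freq_THz >= lo) & (self.freq_THz <= hi)
        return AbsorptionSpectrum(self.freq_THz[m], self.alpha_cm1[m], (lo, hi), self.meta)


def transfer_function(
    sample: ComplexSpectrum,
    reference: ComplexSpectrum,
    band_THz=DEFAULT_BAND_THZ,
) -> TransferFunction:
    """Compute |T̃| and the processed phase difference inside ``band_THz``."""
    if len(sample.freq_THz) != len(reference.freq_THz) or not np.allclose(
        sample.freq_THz, reference.freq_THz, rtol=0, atol=1e-12
    ):
        raise ValueError("sample and reference spectra must share one frequency axis")
    lo, hi = band_THz
    freq = sample.freq_THz
    if lo <= 0 or hi <= lo or hi > freq[-1]:
        raise ValueError(f"band {band_THz} THz must satisfy 0 < lo < hi <= {freq[-1]:.3g}")
    m = (freq >= lo) & (freq <= hi)

    ref_mag = reference.magnitude
    floor = DYNAMIC_RANGE_FLOOR * ref_mag.max()
    weak = m & (ref_mag < floor)
    if weak.any():
        nu_bad = freq[weak][0]
        raise DynamicRangeError(
            f"reference magnitude below dynamic-range floor at {nu_bad:.3f} THz; "
            "narrow the analysis band"
        )

    ratio = sample.field[m] / reference.field[m]
    magnitude = np.abs(ratio)
    # numpy's forward FFT uses exp(-i2πνt): a time delay lowers the phase,
    # so negate to make Δφ the (positive) phase delay of the sample.
    delta_phi = -np.unwrap(np.angle(ratio))
    slope, intercept = np.polyfit(freq[m], delta_phi, 1)
    delta_phi = delta_phi - 2 * np.pi * np.round(intercept / (2 * np.pi))
    return TransferFunction(freq[m], magnitude, delta_phi, (lo, hi), sample.meta)


def refractive_index(tf: TransferFunction, d_mm: float) -> np.ndarray:
    """n(ν) from the processed phase difference; d in millimetres."""
    if d_mm <= 0:
        raise ValueError("thickness must be positive")
    nu_hz = tf.freq_THz * 1e12
    d_m = d_mm * 1e-3
    return 1.0 + C_M_PER_S * tf.delta_phi_rad / (2 * np.pi * nu_hz * d_m)


def absorption_coefficient(tf: TransferFunction, n_of_freq, d_mm: float) -> AbsorptionSpectrum:
    """α(ν) in cm⁻¹ from |T̃| and n(ν), correcting the Fresnel loss (n+1)²/(4n)."""
    if d_mm <= 0:
        raise ValueError("thickness must be positive")
    n = np.broadcast_to(np.asarray(n_of_freq, dtype=float), tf.freq_THz.shape)
    log_arg = (n + 1.0) ** 2 / (4.0 * n) * tf.magnitude
    if np.any(log_arg <= 0):
        nu_bad = tf.freq_THz[np.nonzero(log_arg <= 0)[0][0]]
        raise ValueError(
            f"non-positive Fresnel-corrected magnitude at {nu_bad:.3f} THz; "
            "unphysical transfer function"
        )
    d_m = d_mm * 1e-3
    alpha_m1 = -(2.0 / d_m) * np.log(log_arg)
    return AbsorptionSpectrum(tf.freq_THz, alpha_m1 / 100.0, tf.band_THz, tf.meta)


def extract_optical_constants(
    sample_wf: Waveform,
    reference_wf: Waveform,
    band_THz=DEFAULT_BAND_THZ,
    head_ps: float = 5.0,
    tukey_alpha: float = 0.1,
    pad_factor: int = 4,
) -> OpticalConstants:
    """Full chain from a waveform pair to (n, α) over the analysis band."""
    d_mm = sample_wf.meta.thickness_mm
    if d_mm is None:
        raise ValueError(
            f"sample scan {sample_wf.meta.sample_id!r} lacks thickness_mm; "
            "cannot extract optical constants"
        )
    spec_s = preprocess_waveform(sample_wf, head_ps=head_ps, tukey_alpha=tukey_alpha, pad_factor=pad_factor)
    spec_r = preprocess_waveform(reference_wf, head_ps=head_ps, tukey_alpha=tukey_alpha, pad_factor=pad_factor)
    tf = transfer_function(spec_s, spec_r, band_THz=band_THz)
    n = refractive_index(tf, d_mm)
    absorb = absorption_coefficient(tf, n, d_mm)
    return OpticalConstants(tf.freq_THz, n, absorb.alpha_cm1, d_mm, tf.band_THz, sample_wf.meta)
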