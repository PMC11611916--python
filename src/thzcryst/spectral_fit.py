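"""Spectral decomposition: reference-form models and crystallinity fits.

Crystalline nifedipine shows distinct THz absorption peaks that are well
described by Gaussians riding on a monotonically rising quadratic background
(dominated by scattering); the amorphous form shows the background alone.
Each pure crystalline form is summarized as a ReferenceModel of exactly
three Gaussian peaks plus a quadratic.  Mixtures are then quantified by

    f(ν) = A·Σᵢ G_αᵢ exp(−((ν − ν₀^αᵢ)/Δν_αᵢ)²)
         + B·Σᵢ G_βᵢ exp(−((ν − ν₀^βᵢ)/Δν_βᵢ)²) + (c₀ + c₁ν + c₂ν²)

with every peak parameter FIXED at its reference value, so the fit is
linear in (A, B, c₀, c₁, c₂) and solved as constrained linear least squares
with A, B ≥ 0 — deterministic, with no starting-point sensitivity.

Width convention: Δν is the e-folding half-width of exp(−((ν−ν₀)/Δν)²),
not a Gaussian σ (σ = Δν/√2) and not a FWHM (FWHM = 2√(ln 2)·Δν).

A = B = 1 corresponds to pure-form reference intensity; the coefficients
are relative measures of polymorph content, not absolute mass fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lmfit import Model
from scipy.optimize import lsq_linear
from scipy.signal import find_peaks

from .optics import AbsorptionSpectrum
from .waveform_io import logger

#: Default crystallinity fit band, THz: covers all six nifedipine peaks
#: (0.95–1.50 THz) with margin for the background.
DEFAULT_FIT_BAND_THZ = (0.5, 1.8)


class AmorphousSpectrumError(ValueError):
    """Too few prominent peaks: the spectrum may be amorphous."""


class FitConvergenceError(RuntimeError):
    """Nonlinear reference fit failed to converge."""


def fwhm_from_width(dnu_THz: float) -> float:
    """Convert the e-folding half-width Δν to a full width at half maximum."""
    return 2.0 * np.sqrt(np.log(2.0)) * dnu_THz


def width_from_fwhm(fwhm_THz: float) -> float:
    return fwhm_THz / (2.0 * np.sqrt(np.log(2.0)))


@dataclass(frozen=True)
class GaussianPeak:
    """One absorption line: amplitude G (cm⁻¹), center ν₀ and e-folding width Δν (THz)."""

    G: float
    nu0_THz: float
    dnu_THz: float

    def __post_init__(self):
        if self.G < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.dnu_THz <= 0:
            raise ValueError("peak width must be positive")

    def __call__(self, freq_THz) -> np.ndarray:
        nu = np.asarray(freq_THz, dtype=float)
        return self.G * np.exp(-(((nu - self.nu0_THz) / self.dnu_THz) ** 2))


def peak_sum(peaks, freq_THz) -> np.ndarray:
    """Evaluate the sum of Gaussian peaks on a frequency axis."""
    nu = np.asarray(freq_THz, dtype=float)
    total = np.zeros_like(nu)
    for p in peaks:
        total += p(nu)
    return total


def quadratic(coeffs, freq_THz) -> np.ndarray:
    c0, c1, c2 = coeffs
    nu = np.asarray(freq_THz, dtype=float)
    return c0 + c1 * nu + c2 * nu**2


@dataclass
class ReferenceModel:
    """Three Gaussian peaks + quadratic background for one crystalline form."""

    form: str
    peaks: tuple
    background: tuple
    fit_band_THz: tuple = DEFAULT_FIT_BAND_THZ
    residual_rms_cm1: float = 0.0

    def __post_init__(self):
        if self.form not in ("alpha", "beta"):
            raise ValueError("form must be 'alpha' or 'beta'")
        self.peaks = tuple(sorted(self.peaks, key=lambda p: p.nu0_THz))
        if len(self.peaks) != 3:
            logger.warning("reference model for %s has %d peaks (expected 3)", self.form, len(self.peaks))

    def peak_profile(self, freq_THz) -> np.ndarray:
        """Peak sum only, without the background."""
        return peak_sum(self.peaks, freq_THz)

    def evaluate(self, freq_THz) -> np.ndarray:
        """Full model: peaks plus quadratic background."""
        return self.peak_profile(freq_THz) + quadratic(self.background, freq_THz)

    @property
    def centers_THz(self) -> tuple:
        return tuple(p.nu0_THz for p in self.peaks)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "peaks": [{"G_cm1": p.G, "nu0_THz": p.nu0_THz, "dnu_THz": p.dnu_THz} for p in self.peaks],
            "background_cm1": list(self.background),
            "fit_band_THz": list(self.fit_band_THz),
            "residual_rms_cm1": self.residual_rms_cm1,
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModel":
        peaks = tuple(GaussianPeak(p["G_cm1"], p["nu0_THz"], p["dnu_THz"]) for p in d["peaks"])
        return cls(
            form=d["form"],
            peaks=peaks,
            background=tuple(d["background_cm1"]),
            fit_band_THz=tuple(d["fit_band_THz"]),
            residual_rms_cm1=d.get("residual_rms_cm1", 0.0),
        )

    @classmethod
    def load(cls, path) -> "ReferenceModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CrystallinityFit:
    """Mixture coefficients for one absorption spectrum.

    A tracks the α-form content, B the β-form content, relative to the
    pure-form reference intensity.  The quadratic background is refitted per
    spectrum because the baseline level itself evolves with crystallinity.
    """

    A: float
    B: float
    background: tuple
    residual_rms_cm1: float
    sample_id: str = ""
    temperature_C: float | None = None
    time_h: float = 0.0
    A_unconstrained: float = field(default=np.nan, repr=False)
    B_unconstrained: float = field(default=np.nan, repr=False)

    def __post_init__(self):
        if self.A < 0 or self.B < 0:
            raise ValueError("constrained fit coefficients must be non-negative")


def _gauss3_quad(nu, g1, c1, w1, g2, c2, w2, g3, c3, w3, b0, b1, b2):
    out = b0 + b1 * nu + b2 * nu**2
    for g, c, w in ((g1, c1, w1), (g2, c2, w2), (g3, c3, w3)):
        out = out + g * np.exp(-(((nu - c) / w) ** 2))
    return out


def fit_reference(
    spec: AbsorptionSpectrum,
    form: str,
    n_peaks: int = 3,
    band_THz=DEFAULT_FIT_BAND_THZ,
    prominence_cm1: float = 0.3,
) -> ReferenceModel:
    """Fit a pure-form absorption spectrum with n Gaussians + quadratic.

    Initialization takes the ``n_peaks`` most prominent local maxima of the
    quadratically detrended spectrum.  Bounds keep amplitudes non-negative,
    widths in [0.01, 0.5] THz and centers inside the band.  Finding fewer
    prominent maxima than requested raises AmorphousSpectrumError, since a
    featureless monotonically rising spectrum is the amorphous signature.
    """
    if n_peaks != 3:
        logger.warning("fit_reference called with n_peaks=%d; reference models normally use 3", n_peaks)
    sub = spec.restrict(band_THz)
    nu, y = sub.freq_THz, sub.alpha_cm1
    if len(nu) < 3 * n_peaks + 3:
        raise ValueError("spectrum does not cover the fit band densely enough")

    bg0 = np.polyfit(nu, y, 2)[::-1]  # (c0, c1, c2)
    detrended = y - quadratic(bg0, nu)
    idx, props = find_peaks(detrended, prominence=prominence_cm1)
    if len(idx) < n_peaks:
        raise AmorphousSpectrumError(
            f"found {len(idx)} prominent maxima, need {n_peaks}: "
            "the spectrum may be amorphous (featureless rising absorption)"
        )
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    idx = np.sort(idx[order])

    model = Model(_gauss3_quad, independent_vars=["nu"])
    params = model.make_params()
    lo, hi = band_THz
    for k, i in enumerate(idx, start=1):
        params[f"g{k}"].set(value=max(detrended[i], prominence_cm1), min=0.0)
        params[f"c{k}"].set(value=nu[i], min=lo, max=hi)
        params[f"w{k}"].set(value=0.05, min=0.01, max=0.5)
    for j, b in enumerate(bg0):
        params[f"b{j}"].set(value=b)

    result = model.fit(y, params, nu=nu)
    if not result.success:
        raise FitConvergenceError(
            f"reference fit for {form} did not converge: {result.message} "
            f"(residual rms {np.sqrt(np.mean(result.residual**2)):.3g} cm⁻¹)"
        )
    p = result.params
    peaks = tuple(
        GaussianPeak(p[f"g{k}"].value, p[f"c{k}"].value, p[f"w{k}"].value) for k in range(1, n_peaks + 1)
    )
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return ReferenceModel(
        form=form,
        peaks=peaks,
        background=(p["b0"].value, p["b1"].value, p["b2"].value),
        fit_band_THz=tuple(band_THz),
        residual_rms_cm1=rms,
    )


def fit_crystallinity(
    spec: AbsorptionSpectrum,
    ref_alpha: ReferenceModel,
    ref_beta: ReferenceModel,
    band_THz=DEFAULT_FIT_BAND_THZ,
) -> CrystallinityFit:
    """Solve the fixed-shape mixture model for (A, B) and the background.

    The reference peak parameters are never altered; only the weights A, B
    (constrained non-negative) and the per-spectrum quadratic are free.  The
    unconstrained solution is retained for diagnostics.
    """
    sub = spec.restrict(band_THz)
    nu, y = sub.freq_THz, sub.alpha_cm1
    design = np.column_stack(
        [ref_alpha.peak_profile(nu), ref_beta.peak_profile(nu), np.ones_like(nu), nu, nu**2]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"rank-deficient crystallinity design over band {band_THz} THz")

    unconstrained, *_ = np.linalg.lstsq(design, y, rcond=None)
    res = lsq_linear(
        design,
        y,
        bounds=([0.0, 0.0, -np.inf, -np.inf, -np.inf], [np.inf] * 5),
        method="bvls",
    )
    A, B, c0, c1, c2 = res.x
    rms = float(np.sqrt(np.mean((design @ res.x - y) ** 2)))
    if unconstrained[0] < -1e-9 or unconstrained[1] < -1e-9:
        logger.debug(
            "unconstrained crystallinity solution negative (A=%.4g, B=%.4g) for %s at t=%.2f h",
            unconstrained[0], unconstrained[1], sub.meta.sample_id, sub.meta.time_h,
        )
    return CrystallinityFit(
        A=float(A),
        B=float(B),
        background=(float(c0), float(c1), float(c2)),
        residual_rms_cm1=rms,
        sample_id=sub.meta.sample_id,
        temperature_C=sub.meta.temperature_C,
        time_h=sub.meta.time_h,
        A_unconstrained=float(unconstrained[0]),
        B_unconstrained=float(unconstrained[1]),
    )


def classify_form(
    spec: AbsorptionSpectrum,
    ref_alpha: ReferenceModel,
    ref_beta: ReferenceModel,
    amorphous_threshold: float = 0.05,
    mixed_ratio: tuple = (0.5, 2.0),
    band_THz=DEFAULT_FIT_BAND_THZ,
) -> str:
    """Label a spectrum amorphous / alpha / beta / mixed from its (A, B) fit.

    Amorphous when both coefficients fall below ``amorphous_threshold``;
    otherwise mixed when A/B lies within ``mixed_ratio``, else the dominant
    coefficient names the form.
    """
    fit = fit_crystallinity(spec, ref_alpha, ref_beta, band_THz=band_THz)
    if fit.A < amorphous_threshold and fit.B < amorphous_threshold:
        return "amorphous"
    if fit.B == 0.0:
        return "alpha"
    ratio = fit.A / fit.B
    lo, hi = mixed_ratio
    if lo <= ratio <= hi:
        return "mixed"
    return "alpha" if ratio > hi else "beta"
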