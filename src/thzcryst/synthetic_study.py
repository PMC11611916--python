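"""Synthetic aging studies: kinetics, spectra, waveforms and study trees.

The generator emulates the experiment end to end so every analysis stage is
testable without a spectrometer:

* Phase kinetics — initially amorphous nifedipine crystallizes sequentially,
  amorphous → metastable β → stable α, modeled as first-order steps with
  rates k1, k2 at the 24 °C reference temperature and a Q10 multiplicative
  acceleration per 10 °C of storage.  The closed-form solution of the
  sequential scheme is used throughout (no numerical integration).
* Spectra — each pure form contributes three Gaussian absorption peaks plus
  a quadratic background; the amorphous form contributes a higher featureless
  quadratic (the vibrational-density-of-states baseline collapses as the
  material crystallizes).  A mixture's absorption is the fraction-weighted
  convex combination of the three pure-form spectra.
* Waveforms — a single-cycle THz pulse is transmitted through a
  plano-parallel tablet in the frequency domain: Fresnel factor 4n/(n+1)²,
  Beer–Lambert field attenuation exp(−α·d/2), and the slab phase delay
  exp(−i·2πν·(n−1)·d/c).  The Fresnel factor is the exact reciprocal of the
  (n+1)²/(4n) term used in extraction, so noiseless pairs round-trip.
* Noise — additive white Gaussian noise per raw acquisition, reduced by
  averaging ``n_averages`` records per stored waveform.

Default study protocol: 3 storage temperatures (24/30/35 °C), 5 replicate
tablets each, 144 h of monitoring at a 3.5-min cadence, 100 averages,
tablet thickness drawn once per sample from U(1.1, 1.6) mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_fit import GaussianPeak, ReferenceModel, quadratic
from .waveform_io import MANIFEST_COLUMNS, ScanMeta, Waveform, logger, write_manifest, write_waveform

#: Reference temperature (°C) at which k1, k2 are specified: ambient storage.
REF_TEMPERATURE_C = 24.0

#: Printed peak centers (THz) of the two crystalline forms of nifedipine.
NIF_ALPHA_CENTERS_THZ = (1.09, 1.20, 1.36)
NIF_BETA_CENTERS_THZ = (0.95, 1.25, 1.50)

#: Default synthetic peak amplitudes (cm⁻¹) and e-folding widths (THz); the
#: β-form peaks are the weaker set, matching the observed contrast.
NIF_ALPHA_AMPLITUDES_CM1 = (6.0, 4.0, 5.0)
NIF_ALPHA_WIDTHS_THZ = (0.05, 0.05, 0.07)
NIF_BETA_AMPLITUDES_CM1 = (2.5, 3.0, 1.8)
NIF_BETA_WIDTHS_THZ = (0.06, 0.07, 0.09)

#: Quadratic background coefficients (c0, c1, c2), α in cm⁻¹ for ν in THz.
#: The amorphous baseline sits well above the crystalline one.
DEFAULT_AMORPHOUS_BACKGROUND = (2.0, 3.0, 2.5)
DEFAULT_CRYSTALLINE_BACKGROUND = (1.0, 1.5, 1.25)

#: Frequency-independent refractive index per form (the synthetic tablets
#: are dispersionless; all spectral structure lives in the absorption).
FORM_REFRACTIVE_INDEX = {"amorphous": 1.6, "beta": 1.7, "alpha": 1.8}

#: Tablet thickness range, mm.
THICKNESS_RANGE_MM = (1.1, 1.6)


def default_reference_model(form: str) -> ReferenceModel:
    """Synthetic pure-form reference model built on the printed peak centers."""
    if form == "alpha":
        centers, amps, widths = NIF_ALPHA_CENTERS_THZ, NIF_ALPHA_AMPLITUDES_CM1, NIF_ALPHA_WIDTHS_THZ
    elif form == "beta":
        centers, amps, widths = NIF_BETA_CENTERS_THZ, NIF_BETA_AMPLITUDES_CM1, NIF_BETA_WIDTHS_THZ
    else:
        raise ValueError("form must be 'alpha' or 'beta'")
    peaks = tuple(GaussianPeak(g, c, w) for g, c, w in zip(amps, centers, widths))
    return ReferenceModel(form=form, peaks=peaks, background=DEFAULT_CRYSTALLINE_BACKGROUND)


@dataclass(frozen=True)
class PhaseFractions:
    """Mass fractions of the three solid-state forms at one timepoint."""

    x_amorphous: float
    x_beta: float
    x_alpha: float

    def __post_init__(self):
        for name, x in (
            ("x_amorphous", self.x_amorphous),
            ("x_beta", self.x_beta),
            ("x_alpha", self.x_alpha),
        ):
            if not -1e-12 <= x <= 1 + 1e-12:
                raise ValueError(f"{name} = {x} outside [0, 1]")
        total = self.x_amorphous + self.x_beta + self.x_alpha
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total})")

    def mixture_index(self, form_n=None) -> float:
        """Fraction-weighted refractive index of the tablet."""
        n = form_n or FORM_REFRACTIVE_INDEX
        return (
            self.x_amorphous * n["amorphous"] + self.x_beta * n["beta"] + self.x_alpha * n["alpha"]
        )


@dataclass(frozen=True)
class KineticsParams:
    """Sequential first-order crystallization kinetics with Q10 scaling.

    Defaults put the β-coefficient peak at 100 h for 24 °C storage and, with
    q10_factor = 8, near 29 h at 30 °C and 10 h at 35 °C — the observed
    ordering of an intermediate metastable step that accelerates strongly
    with temperature.
    """

    k1_per_hour: float = np.log(2) / 100.0  # amorphous → β at 24 °C
    k2_per_hour: float = np.log(2) / 50.0  # β → α at 24 °C
    temperatures_C: tuple = (24.0, 30.0, 35.0)
    q10_factor: float = 8.0
    duration_h: float = 144.0
    cadence_min: float = 3.5
    n_replicates: int = 5

    def __post_init__(self):
        if self.k1_per_hour <= 0 or self.k2_per_hour <= 0:
            raise ValueError("rate constants must be positive")
        if self.q10_factor <= 0:
            raise ValueError("q10_factor must be positive")
        if self.duration_h <= 0 or self.cadence_min <= 0:
            raise ValueError("duration and cadence must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def rates_at(self, temperature_C: float) -> tuple[float, float]:
        scale = self.q10_factor ** ((temperature_C - REF_TEMPERATURE_C) / 10.0)
        return self.k1_per_hour * scale, self.k2_per_hour * scale

    def timepoints_h(self) -> np.ndarray:
        cadence_h = self.cadence_min / 60.0
        n_steps = int(np.floor(self.duration_h / cadence_h + 1e-9))
        return np.arange(n_steps + 1) * cadence_h


@dataclass(frozen=True)
class PulseParams:
    """Synthetic single-cycle reference pulse and acquisition settings.

    The pulse is the derivative of a Gaussian (one positive and one negative
    lobe), normalized to peak amplitude ``amplitude_au``; its spectrum peaks
    near 1/(2π·width) ≈ 1 THz for the default width, covering the 0.3–2 THz
    analysis band.  ``noise_std_au`` is the additive white-noise level of a
    single raw acquisition; stored waveforms average ``n_averages`` of them.
    """

    center_time_ps: float = 10.0
    width_ps: float = 0.15
    amplitude_au: float = 1.0
    time_window_ps: float = 60.0
    dt_ps: float = 0.05
    noise_std_au: float = 0.01
    n_averages: int = 100

    def __post_init__(self):
        if self.dt_ps <= 0 or self.time_window_ps <= 0 or self.width_ps <= 0:
            raise ValueError("dt_ps, time_window_ps and width_ps must be positive")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.noise_std_au < 0:
            raise ValueError("noise_std_au must be non-negative")

    def time_axis_ps(self) -> np.ndarray:
        n = int(round(self.time_window_ps / self.dt_ps))
        return np.arange(n) * self.dt_ps

    def clean_pulse(self) -> np.ndarray:
        """Noise-free single-cycle transient on the record's time axis."""
        t = self.time_axis_ps()
        u = (t - self.center_time_ps) / self.width_ps
        # derivative-of-Gaussian, peak-normalized (extremum at u = ±1)
        return -self.amplitude_au * u * np.exp(-(u**2) / 2.0) / np.exp(-0.5)

    @property
    def effective_noise_std(self) -> float:
        return self.noise_std_au / np.sqrt(self.n_averages)


def simulate_kinetics(params: KineticsParams, temperature_C: float, times_h) -> list[PhaseFractions]:
    """Closed-form phase fractions of the sequential first-order scheme.

    x_a' = −k1·x_a, x_β' = k1·x_a − k2·x_β, x_α' = k2·x_β, starting from a
    fully amorphous tablet.  The k1 = k2 degeneracy uses the limit expression
    x_β = k·t·e^(−k·t) rather than the generic formula's 0/0.
    """
    times_h = np.asarray(times_h, dtype=float)
    if np.any(times_h < 0) or np.any(np.diff(times_h) < 0):
        raise ValueError("times must be non-negative and non-decreasing")
    k1, k2 = params.rates_at(temperature_C)
    xa = np.exp(-k1 * times_h)
    if abs(k1 - k2) <= 1e-12 * max(k1, k2):
        xb = k1 * times_h * np.exp(-k1 * times_h)
    else:
        xb = k1 / (k2 - k1) * (np.exp(-k1 * times_h) - np.exp(-k2 * times_h))
    xb = np.clip(xb, 0.0, 1.0)
    xal = np.clip(1.0 - xa - xb, 0.0, 1.0)
    return [PhaseFractions(float(a), float(b), float(c)) for a, b, c in zip(xa, xb, xal)]


def compose_absorption(
    fractions: PhaseFractions,
    ref_alpha: ReferenceModel,
    ref_beta: ReferenceModel,
    amorphous_background,
    freq_THz,
) -> np.ndarray:
    """Mixture absorption spectrum (cm⁻¹) on ``freq_THz``.

    Convex combination of the pure-form spectra: the amorphous quadratic,
    and each crystalline form's peaks plus its (lower) quadratic background.
    The baseline therefore interpolates linearly from the amorphous level
    down to the crystalline level as the total crystalline fraction grows.
    """
    nu = np.asarray(freq_THz, dtype=float)
    if np.any(nu < 0) or np.any(np.diff(nu) <= 0):
        raise ValueError("frequency axis must be non-negative and increasing")
    f = fractions
    return (
        f.x_amorphous * quadratic(amorphous_background, nu)
        + f.x_beta * (ref_beta.peak_profile(nu) + quadratic(ref_beta.background, nu))
        + f.x_alpha * (ref_alpha.peak_profile(nu) + quadratic(ref_alpha.background, nu))
    )


def _slab_transmission(freq_THz, n_arr, alpha_cm1_arr, d_mm) -> np.ndarray:
    """Complex field transmission of a plano-parallel slab (no etalon echoes)."""
    from .optics import C_M_PER_S

    d_m = d_mm * 1e-3
    nu_hz = np.asarray(freq_THz) * 1e12
    alpha_m1 = np.asarray(alpha_cm1_arr) * 100.0
    fresnel = 4.0 * n_arr / (n_arr + 1.0) ** 2
    return fresnel * np.exp(-alpha_m1 * d_m / 2.0) * np.exp(-1j * 2 * np.pi * nu_hz * (n_arr - 1.0) * d_m / C_M_PER_S)


def _evaluate_on_grid(fn_or_value, freq_THz) -> np.ndarray:
    if callable(fn_or_value):
        out = np.asarray(fn_or_value(freq_THz), dtype=float)
    else:
        out = np.asarray(fn_or_value, dtype=float)
    return np.broadcast_to(out, np.shape(freq_THz)).astype(float)


def synthesize_waveform_pair(
    n_of_freq,
    alpha_of_freq,
    d_mm: float,
    pulse: PulseParams = PulseParams(),
    seed: int | None = None,
    meta: ScanMeta | None = None,
) -> tuple[Waveform, Waveform]:
    """Synthesize a (reference, sample) waveform pair for one tablet.

    ``n_of_freq`` and ``alpha_of_freq`` may be callables of the frequency
    axis (THz), scalars, or arrays on the record's rfft grid; α in cm⁻¹.
    Returns the pair with independent averaged noise on each waveform.
    """
    if d_mm <= 0:
        raise ValueError("thickness must be positive")
    t = pulse.time_axis_ps()
    clean = pulse.clean_pulse()
    freq = np.fft.rfftfreq(len(t), d=pulse.dt_ps)
    n_arr = _evaluate_on_grid(n_of_freq, freq)
    a_arr = _evaluate_on_grid(alpha_of_freq, freq)
    if np.any(n_arr < 1.0):
        raise ValueError("refractive index must be >= 1")
    if np.any(a_arr < 0):
        raise ValueError("absorption coefficient must be non-negative")

    from .optics import C_M_PER_S

    delay_ps = (n_arr.max() - 1.0) * d_mm * 1e-3 / C_M_PER_S * 1e12
    needed = pulse.center_time_ps + delay_ps + 8.0 * pulse.width_ps
    if needed > pulse.time_window_ps:
        raise ValueError(
            f"delayed sample pulse leaves the record: need time_window_ps >= {needed:.1f} ps "
            f"(have {pulse.time_window_ps:g} ps)"
        )

    field = np.fft.rfft(clean)
    sample_clean = np.fft.irfft(field * _slab_transmission(freq, n_arr, a_arr, d_mm), n=len(t))

    rng = np.random.default_rng(seed)
    sigma = pulse.effective_noise_std
    if sigma > 0:
        ref_amp = clean + rng.normal(0.0, sigma, len(t))
        smp_amp = sample_clean + rng.normal(0.0, sigma, len(t))
    else:
        ref_amp, smp_amp = clean, sample_clean

    base = meta or ScanMeta()
    ref_meta = ScanMeta(
        sample_id=base.sample_id, role="reference", thickness_mm=None,
        temperature_C=base.temperature_C, time_h=base.time_h, n_averages=pulse.n_averages,
    )
    smp_meta = ScanMeta(
        sample_id=base.sample_id, role="sample", thickness_mm=d_mm,
        temperature_C=base.temperature_C, time_h=base.time_h, n_averages=pulse.n_averages,
    )
    return Waveform(t, ref_amp, ref_meta), Waveform(t, smp_amp, smp_meta)


@dataclass
class StudyRefs:
    """Pure-form models and backgrounds driving the forward simulation."""

    ref_alpha: ReferenceModel = field(default_factory=lambda: default_reference_model("alpha"))
    ref_beta: ReferenceModel = field(default_factory=lambda: default_reference_model("beta"))
    amorphous_background: tuple = DEFAULT_AMORPHOUS_BACKGROUND
    form_n: dict = field(default_factory=lambda: dict(FORM_REFRACTIVE_INDEX))


def generate_study(
    kinetics: KineticsParams = KineticsParams(),
    refs: StudyRefs | None = None,
    pulse: PulseParams = PulseParams(),
    out_dir="study",
    seed: int = 0,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write a complete synthetic aging study tree and return its manifest.

    Layout: one directory per temperature containing a ``reference/``
    directory (one reference waveform per acquisition cycle) and one
    directory per replicate (one sample waveform per timepoint).  Thickness
    is drawn once per sample from U(1.1, 1.6) mm and held fixed.  The
    manifest records every file with its ground-truth phase fractions.

    Identical (configuration, seed) inputs produce a byte-identical tree:
    every random stream is keyed on (seed, temperature index, replicate,
    cycle) so generation order is immaterial.
    """
    refs = refs or StudyRefs()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True to replace")
    out_dir.mkdir(parents=True, exist_ok=True)

    times = kinetics.timepoints_h()
    t_axis = pulse.time_axis_ps()
    clean = pulse.clean_pulse()
    field_clean = np.fft.rfft(clean)
    freq = np.fft.rfftfreq(len(t_axis), d=pulse.dt_ps)
    sigma = pulse.effective_noise_std

    rows = []
    for ti, temp in enumerate(kinetics.temperatures_C):
        temp_dir = out_dir / f"T{temp:g}C"
        ref_dir = temp_dir / "reference"
        ref_dir.mkdir(parents=True, exist_ok=True)
        fractions = simulate_kinetics(kinetics, temp, times)

        for ci, t_h in enumerate(times):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(ti, 0, ci)))
            amp = clean + rng.normal(0.0, sigma, len(t_axis)) if sigma > 0 else clean
            meta = ScanMeta(
                sample_id=f"T{temp:g}C_ref", role="reference", temperature_C=temp,
                time_h=float(t_h), n_averages=pulse.n_averages,
            )
            path = ref_dir / f"cycle{ci:04d}.txt"
            write_waveform(Waveform(t_axis, amp, meta), path)
            rows.append(
                dict(file=str(path.relative_to(out_dir)), role="reference", temperature_C=temp,
                     replicate=np.nan, time_h=float(t_h), thickness_mm=np.nan,
                     x_amorphous=np.nan, x_beta=np.nan, x_alpha=np.nan, seed=seed)
            )

        for ri in range(1, kinetics.n_replicates + 1):
            rng_d = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(ti, ri, 999_999)))
            d_mm = float(rng_d.uniform(*THICKNESS_RANGE_MM))
            rep_dir = temp_dir / f"rep{ri}"
            rep_dir.mkdir(parents=True, exist_ok=True)
            sample_id = f"T{temp:g}C_r{ri}"

            for ci, (t_h, frac) in enumerate(zip(times, fractions)):
                alpha = compose_absorption(frac, refs.ref_alpha, refs.ref_beta, refs.amorphous_background, freq)
                n_mix = frac.mixture_index(refs.form_n)
                trans = _slab_transmission(freq, np.full_like(freq, n_mix), alpha, d_mm)
                amp = np.fft.irfft(field_clean * trans, n=len(t_axis))
                if sigma > 0:
                    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(ti, ri, ci)))
                    amp = amp + rng.normal(0.0, sigma, len(t_axis))
                meta = ScanMeta(
                    sample_id=sample_id, role="sample", thickness_mm=d_mm,
                    temperature_C=temp, time_h=float(t_h), n_averages=pulse.n_averages,
                )
                path = rep_dir / f"t{ci:04d}.txt"
                write_waveform(Waveform(t_axis, amp, meta), path)
                rows.append(
                    dict(file=str(path.relative_to(out_dir)), role="sample", temperature_C=temp,
                         replicate=ri, time_h=float(t_h), thickness_mm=d_mm,
                         x_amorphous=frac.x_amorphous, x_beta=frac.x_beta,
                         x_alpha=frac.x_alpha, seed=seed)
                )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    write_manifest(manifest, out_dir / "manifest.tsv")
    logger.info(
        "generated study in %s: %d waveforms (%d temperatures × %d replicates × %d timepoints)",
        out_dir, len(manifest), len(kinetics.temperatures_C), kinetics.n_replicates, len(times),
    )
    return manifest
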