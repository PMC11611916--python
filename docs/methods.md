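# Methods

This note records the models, numerical choices and known limitations of
`thzcryst`, in the order data flows through the package.

## Synthetic studies

No public THz-TDS dataset of recrystallizing nifedipine tablets exists, so
the package ships a forward model of the experiment whose statistical
structure matches what the analysis assumes.

**Phase kinetics.** An initially amorphous tablet converts sequentially,
amorphous → β → α, modeled as two first-order steps:

    x_a' = −k1·x_a,   x_β' = k1·x_a − k2·x_β,   x_α' = k2·x_β

solved in closed form (the k1 = k2 degeneracy uses the limit expression
x_β = k·t·e^{−kt}, whose maximum is at t = 1/k). Storage temperature
enters through a Q10 law: both rates are multiplied by
`q10_factor^((T − 24 °C)/10)`. Defaults are `k1 = ln2/100 h⁻¹`,
`k2 = 2·k1` (so the β coefficient peaks at exactly 100 h at 24 °C) and
`q10_factor = 8`, which places the β-peak near 29 h at 30 °C and 10 h at
35 °C — reproducing the observed ordering of a metastable intermediate
that appears and converts markedly faster at higher storage temperature.
A single Q10 exponent cannot match all three observed timescales at once;
the value 8 is the log-time least-squares compromise and is deliberately
not refitted elsewhere. This is a phenomenological stand-in: real
nucleation-and-growth kinetics are sigmoidal (Avrami-type) and
sample-history-dependent, which the first-order scheme does not attempt to
capture.

**Spectra.** Each crystalline form contributes three Gaussian absorption
peaks plus a quadratic scattering background; the amorphous form
contributes a larger featureless quadratic (defaults: amorphous
(2.0, 3.0, 2.5), crystalline (1.0, 1.5, 1.25) in cm⁻¹ per THz power). The
published peak centers fix the default models (α: 1.09/1.20/1.36 THz, β:
0.95/1.25/1.50 THz); amplitudes and e-folding widths are package defaults
chosen inside plausible ranges (α amplitudes 4–6 cm⁻¹, widths
0.05–0.07 THz; β amplitudes 1.8–3 cm⁻¹ — the weaker set — widths
0.06–0.09 THz) because the measured values are not published in the main
text of the source study. A mixture's absorption is the fraction-weighted
convex combination of the three pure-form spectra, so the baseline drops
linearly from the amorphous to the crystalline level as total
crystallinity grows — a linear proxy for the collapse of the
vibrational density of states; it ignores any nonlinearity of that
collapse and any peak shifting or narrowing during crystal maturation.

**Waveforms.** The reference pulse is a derivative-of-Gaussian single
cycle (default center 10 ps, width 0.15 ps, 60 ps record at dt = 0.05 ps),
whose spectrum peaks near 1 THz and covers the 0.3–2.0 THz analysis band.
The sample waveform is built in the frequency domain:

    Ẽ_sample = Ẽ_ref · 4n/(n+1)² · e^{−α·d/2} · e^{−i·2πν·(n−1)·d/c}

— exactly the reciprocal of the extraction formulas, so noiseless pairs
round-trip to machine precision (verified over a grid of n and α). The
refractive index is constant per form (amorphous 1.6, β 1.7, α 1.8,
fraction-weighted for mixtures); all frequency structure lives in α. This
ignores Kramers–Kronig dispersion around the absorption lines, etalon
echoes, beam effects and humidity lines — none of which the analysis
modules claim to handle either, so passing tests demonstrate correctness
of the inversion chain, not robustness to instrument artifacts absent
from the forward model.

**Noise and determinism.** Each raw acquisition carries additive white
Gaussian noise (default σ = 1% of the pulse peak); a stored waveform is
the average of `n_averages = 100` acquisitions, implemented as one draw
with σ/√N (identical in distribution to averaging N draws). Every random
stream is keyed on (seed, temperature index, replicate, cycle), making a
study tree byte-identical for identical configuration and seed,
independent of generation order.

**Protocol defaults.** Three storage temperatures (24/30/35 °C), five
replicate tablets each, 144 h at a 3.5-min per-sample cadence, one
reference scan per acquisition cycle (the protocol does not pin down
reference cadence; per-cycle is assumed), tablet thickness drawn once per
sample from U(1.1, 1.6) mm. Tests and the study-scale acceptance checks
run the same generator scaled to 48 h at a 15-min cadence, which preserves
every qualitative feature being asserted (peak ordering, final-state
dominance) at a fraction of the waveform count.

## Preprocessing

DC offset is the mean over the half-open first 5 ps of the record, which
the generator guarantees is pre-pulse. The Tukey taper parameter defaults
to 0.1 (mild, energy-preserving); records are zero-padded to 4× the next
power of two before an unscaled forward rfft. Neither the taper nor the
pad factor is critical: padding only densifies the frequency sampling
(checked: 4× vs 8× agree within 0.5% at shared bins), and both are applied
identically to sample and reference so any normalization cancels in the
transfer function.

## Optical constants

Extraction is evaluated strictly inside an analysis band (default
0.3–2.0 THz): the phase formula is singular at ν = 0 and reference bins
below 10⁻⁶ of the peak reference magnitude are treated as outside the
instrument's dynamic range (an error, not a silent truncation). Phase
processing unwraps the phase of T̃ upward from the lowest in-band
frequency, negates it so a delayed pulse has positive phase delay, then
shifts by the multiple of 2π nearest the intercept of a linear fit over
the band — the standard branch fix that forces the extrapolated Δφ(ν)
through the origin. Internal units are SI; α is reported in cm⁻¹.
Thickness is read from scan metadata and never fitted (no
self-calibration, no Fabry–Pérot correction).

## Spectral fitting

`fit_reference` is the only nonlinear fit in the package (Levenberg–
Marquardt via lmfit): three Gaussians plus a quadratic, initialized from
the three most prominent maxima of the quadratically detrended spectrum
(prominence threshold 0.3 cm⁻¹), with bounds G ≥ 0, Δν ∈ [0.01, 0.5] THz,
centers inside the fit band. Fewer than three prominent maxima raises an
error suggesting the spectrum is amorphous rather than returning a
degenerate fit. The width convention is the e-folding half-width Δν of
`exp(−((ν−ν₀)/Δν)²)` — σ = Δν/√2, FWHM = 2√(ln 2)·Δν; converters are
provided.

`fit_crystallinity` holds every peak parameter fixed and solves the
resulting linear model by bounded-variable least squares (A, B ≥ 0 —
negative polymorph content is unphysical; the unconstrained solution is
kept for diagnostics). The fit band defaults to 0.5–1.8 THz, bracketing
all six peaks. The background quadratic is refitted per spectrum and never
carried between timepoints, because the baseline itself evolves with
crystallinity. A and B are reported raw — relative to pure-form reference
intensity, with no normalization to A + B + amorphous = 1.

## Kinetics monitoring

Series are decimated by keeping indices 0, k, 2k, … (default k = 4; at the
3.5-min cadence this is the 14-min evaluation interval). Replicates are
aggregated by pointwise mean and *population* standard deviation; grids
must agree within 1 min (sequential acquisition staggers samples by
seconds) — an explicit tolerance instead of silent interpolation. The
B-peak time applies a 5-point centered moving average (edges repeated)
before taking the earliest global maximum; the smoother makes an estimate
read by eye reproducible. Plateau detection at the lowest temperature is
deliberately out of scope: in a truncated window the reported "peak" of a
still-rising series is the window end.

## Pipeline

Stage outputs are files (study tree, reference-model JSON, optics table,
fits table, aggregate tables, JSON report with a configuration hash), so
each stage is re-runnable and the whole run is byte-reproducible under a
fixed seed. Reference models are built inside the pipeline by synthesizing
noiseless pure-form tablets and fitting them — mirroring the experimental
step of measuring pure α- and β-form tablets before the aging study. The
every-4th decimation is applied when selecting which acquisitions to
evaluate (as in the protocol), not after fitting; the series-level
`decimate` operation remains available for already-assembled series.
Configuration is a strict-keys YAML mapping: unknown keys fail validation
before any stage runs.

## Known limitations

* First-order kinetics and linear baseline interpolation are stand-ins for
  mechanisms the source phenomenology does not constrain quantitatively.
* Synthetic peak amplitudes/widths are plausible defaults, not measured
  values; conclusions about absolute A/B magnitudes transfer to real data
  only after refitting references from measured pure-form tablets.
* The extraction chain assumes a single-pass plano-parallel slab: no
  etalon echoes, scattering anisotropy, humidity lines or drift.
* A/B are relative intensities; absolute crystallinity calibration against
  known-content mixtures is out of scope.
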