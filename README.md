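# thzcryst

In-situ crystallinity analysis of pharmaceutical tablets from terahertz
time-domain spectroscopy (THz-TDS) waveforms: from raw electric-field
transients to time-resolved polymorph quantification.

Amorphous drug formulations dissolve better than their crystalline
counterparts but are thermodynamically unstable: during storage they
recrystallize, often through a metastable intermediate, and lose
bioavailability. Crystalline phases have sharp phonon resonances in the
0.1–10 THz band, while amorphous solids show only a featureless, rising
absorption — so transmission THz-TDS can follow crystallization
non-destructively, tablet by tablet, over days. `thzcryst` implements the
complete analysis for such accelerated-aging studies of nifedipine (a
poorly soluble calcium-channel blocker with a stable α and a metastable β
polymorph), plus a synthetic-study generator that emulates the instrument
so the whole chain is testable at a desk.

## The analysis

For each scan, a sample transient `E_sample(t)` and an empty-aperture
reference `E_reference(t)` are conditioned (DC offset from the first 5 ps
removed, Tukey-windowed, zero-padded) and Fourier-transformed. The complex
transfer function `T̃(ν) = Ẽ_sample/Ẽ_reference` of a plano-parallel
tablet of thickness `d` then yields the refractive index and absorption
coefficient

    n(ν) = 1 + c·Δφ(ν)/(2πν·d)
    α(ν) = −(2/d)·ln( (n+1)²/(4n) · |T̃(ν)| )

where `Δφ` is the unwrapped, branch-corrected phase difference and
`(n+1)²/(4n)` removes the Fresnel interface loss.

Each pure crystalline form is summarized once as three Gaussian peaks plus
a quadratic background (α-nifedipine: 1.09, 1.20, 1.36 THz; β-nifedipine:
0.95, 1.25, 1.50 THz). Every time-resolved spectrum is then fitted with

    f(ν) = A·Σᵢ G_αᵢ e^{−((ν−ν₀^αᵢ)/Δν_αᵢ)²} + B·Σᵢ G_βᵢ e^{−((ν−ν₀^βᵢ)/Δν_βᵢ)²} + O(2)

with all peak parameters fixed at their reference values, so the fit is
linear in `(A, B, c₀, c₁, c₂)` and solved exactly by constrained linear
least squares with `A, B ≥ 0`. The coefficients A and B track the α- and
β-form content over time; replicate tablets are aggregated into
mean ± standard-deviation bands and the B-peak time summarizes how fast
the metastable intermediate forms and converts.

## Worked example

Quantifying a mixture that is 60% α and 25% β by reference intensity, with
0.2 cm⁻¹ detector noise (`examples/03_fit_crystallinity.py`):

```text
A = 0.610 (true 0.60)   B = 0.251 (true 0.25)
residual rms = 0.200 cm^-1   classified as: alpha
```

A and B are relative to pure-form reference intensity (A = 1 means the α
peaks are as strong as in a pure α tablet); they are content measures, not
mass fractions. The residual rms at the injected noise level indicates the
fixed-shape model accounts for everything except noise.

Running a scaled aging study end to end (`examples/04_monitor_kinetics.py`)
prints the B-peak time per storage temperature:

```text
B-peak time by storage temperature:
    24 C :   3.5 h
    30 C :   1.5 h
    35 C :   1.0 h
```

— the metastable form appears and hands over to the stable form earlier at
higher temperature, the signature the study protocol is designed to detect.

The other examples cover study generation (`01`) and optical-constant
extraction accuracy (`02`). A thin CLI mirrors the pipeline stages:
`thzcryst simulate | preprocess | extract | fit-reference | fit | monitor |
run-all` (see `thzcryst --help`).

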