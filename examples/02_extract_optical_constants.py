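"""Extract n(nu) and alpha(nu) from a synthetic tablet measurement.

Synthesizes a noiseless waveform pair for a 1.3 mm tablet of the stable
alpha form (constant n = 1.8), runs the preprocessing and transfer-function
chain, and reports how well the known optical constants are recovered.
"""

import numpy as np

from thzcryst import PulseParams, default_reference_model, extract_optical_constants, synthesize_waveform_pair

model = default_reference_model("alpha")
pulse = PulseParams(noise_std_au=0.0)
ref_wf, smp_wf = synthesize_waveform_pair(1.8, model.evaluate, 1.3, pulse)

oc = extract_optical_constants(smp_wf, ref_wf, band_THz=(0.3, 2.0))
true_alpha = model.evaluate(oc.freq_THz)

print(f"analysis band: {oc.band_THz[0]}-{oc.band_THz[1]} THz, {len(oc.freq_THz)} bins")
print(f"recovered n: {oc.n.mean():.4f} (true 1.8000)")
print(f"max |alpha error|: {np.abs(oc.alpha_cm1 - true_alpha).max():.4f} cm^-1")
for nu0 in model.centers_THz:
    i = np.argmin(np.abs(oc.freq_THz - nu0))
    print(f"  alpha({nu0:.2f} THz) = {oc.alpha_cm1[i]:6.2f} cm^-1 (true {true_alpha[i]:6.2f})")
# The three absorption peaks of the alpha form sit on the quadratic
# scattering background; sub-0.1 cm^-1 agreement shows the Fresnel and
# phase processing invert the synthesis exactly.
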