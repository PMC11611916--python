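"""Generate a small synthetic aging study and inspect its manifest.

Three temperatures, two replicate tablets each, 4 h of monitoring at a
30-min cadence.  Every waveform is written as plain text together with a
manifest that records the ground-truth phase fractions of each scan.
"""

import tempfile
from pathlib import Path

from thzcryst import KineticsParams, generate_study

out = Path(tempfile.mkdtemp()) / "study"
kinetics = KineticsParams(
    temperatures_C=(24.0, 30.0, 35.0),
    n_replicates=2,
    duration_h=4.0,
    cadence_min=30.0,
    # accelerated rates so conversion is visible within 4 h
    k1_per_hour=0.3,
    k2_per_hour=0.6,
)
manifest = generate_study(kinetics, out_dir=out, seed=42)

samples = manifest[manifest.role == "sample"]
print(f"study tree: {out}")
print(f"{len(manifest)} waveforms ({len(samples)} sample scans)")
print("\nlast timepoint per temperature (ground-truth fractions):")
final = samples[samples.time_h == samples.time_h.max()]
print(
    final.groupby("temperature_C")[["x_amorphous", "x_beta", "x_alpha"]]
    .mean()
    .round(3)
)
# Higher storage temperature -> more of the stable alpha form at study end.
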