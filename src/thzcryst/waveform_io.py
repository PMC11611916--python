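"""Reading and writing of THz waveforms, study manifests and result tables.

The on-disk waveform dialect is deliberately plain text so that study trees
diff cleanly: a header of ``# key: value`` lines carrying the scan metadata,
followed by two tab-separated columns ``time_ps`` and ``amplitude_au``.
Floats are written with 9 significant digits in a fixed format, so writing
the same waveform twice produces identical bytes.

Units are fixed at this boundary and never converted downstream: time in
picoseconds, thickness in millimetres, temperature in degrees Celsius,
elapsed study time in hours.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("thzcryst")

#: Canonical manifest columns, in writing order.  Ground-truth phase
#: fractions are optional on read (absent for real instrument data).
MANIFEST_COLUMNS = [
    "file",
    "role",
    "temperature_C",
    "replicate",
    "time_h",
    "thickness_mm",
    "x_amorphous",
    "x_beta",
    "x_alpha",
    "seed",
]

_FLOAT_FMT = "%.8e"  # 9 significant digits


class WaveformFormatError(ValueError):
    """Raised when a waveform file violates the documented dialect."""


class ManifestError(ValueError):
    """Raised for malformed or inconsistent study manifests."""


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition metadata attached to one stored waveform.

    ``thickness_mm`` is the tablet thickness d entering the optical-constant
    formulas; it is mandatory for sample scans and meaningless for reference
    scans (an empty slot in the sample magazine).
    """

    sample_id: str = ""
    role: str = "sample"
    thickness_mm: float | None = None
    temperature_C: float | None = None
    time_h: float = 0.0
    n_averages: int = 1

    def __post_init__(self):
        if self.role not in ("sample", "reference"):
            raise WaveformFormatError(f"unknown scan role {self.role!r}")
        if self.role == "sample" and self.thickness_mm is not None and self.thickness_mm <= 0:
            raise WaveformFormatError("thickness_mm must be positive for sample scans")
        if self.time_h < 0:
            raise WaveformFormatError("time_h must be non-negative")


@dataclass
class Waveform:
    """A uniformly sampled THz electric-field transient.

    Attributes
    ----------
    time_ps : ndarray
        Strictly increasing, uniform sample times in picoseconds.
    amplitude_au : ndarray
        Real field amplitudes in arbitrary units.
    meta : ScanMeta
    """

    time_ps: np.ndarray
    amplitude_au: np.ndarray
    meta: ScanMeta = field(default_factory=ScanMeta)

    def __post_init__(self):
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.amplitude_au = np.asarray(self.amplitude_au, dtype=float)
        if self.time_ps.ndim != 1 or self.time_ps.shape != self.amplitude_au.shape:
            raise WaveformFormatError("time and amplitude must be 1-D arrays of equal length")
        if len(self.time_ps) < 64:
            raise WaveformFormatError(f"waveform too short ({len(self.time_ps)} < 64 samples)")
        dt = np.diff(self.time_ps)
        if np.any(dt <= 0):
            raise WaveformFormatError("time axis must be strictly increasing")
        dt0 = dt[0]
        if np.any(np.abs(dt - dt0) > 1e-9 * dt0):
            raise WaveformFormatError("time axis must be uniform (within 1e-9 relative spacing)")

    @property
    def dt_ps(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])

    @property
    def span_ps(self) -> float:
        return float(self.time_ps[-1] - self.time_ps[0])

    def with_amplitude(self, amplitude: np.ndarray, **meta_updates) -> "Waveform":
        meta = replace(self.meta, **meta_updates) if meta_updates else self.meta
        return Waveform(self.time_ps.copy(), np.asarray(amplitude, dtype=float), meta)


_META_KEYS = {
    "sample_id": str,
    "role": str,
    "thickness_mm": float,
    "temperature_C": float,
    "time_h": float,
    "n_averages": int,
}


def write_waveform(wf: Waveform, path) -> Path:
    """Write ``wf`` to ``path`` in the documented text dialect.

    Output is deterministic: fixed key order, fixed float format.  Non-finite
    amplitudes are refused rather than silently serialized.
    """
    path = Path(path)
    if not np.all(np.isfinite(wf.amplitude_au)):
        raise WaveformFormatError(f"refusing to write non-finite amplitudes to {path}")
    m = wf.meta
    lines = [f"# sample_id: {m.sample_id}", f"# role: {m.role}"]
    if m.thickness_mm is not None:
        lines.append(f"# thickness_mm: {m.thickness_mm:.9g}")
    if m.temperature_C is not None:
        lines.append(f"# temperature_C: {m.temperature_C:.9g}")
    lines.append(f"# time_h: {m.time_h:.9g}")
    lines.append(f"# n_averages: {m.n_averages:d}")
    buf = io.StringIO()
    buf.write("\n".join(lines) + "\n")
    np.savetxt(buf, np.column_stack([wf.time_ps, wf.amplitude_au]), fmt=_FLOAT_FMT, delimiter="\t")
    try:
        path.write_text(buf.getvalue())
    except OSError as exc:
        raise OSError(f"failed to write waveform to {path}: {exc}") from exc
    return path


def read_waveform(path) -> Waveform:
    """Read a waveform file, validating the dialect and the time axis.

    Metadata defaults are applied for absent keys (role defaults to
    ``sample``); a sample scan without a recorded thickness is an error,
    since the absorption coefficient cannot be computed without d.
    """
    path = Path(path)
    meta_raw: dict[str, str] = {}
    data_lines: list[str] = []
    first_data_lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta_raw[key.strip()] = value.strip()
                continue
            if not first_data_lineno:
                first_data_lineno = lineno
            data_lines.append(line)

    values = np.empty((len(data_lines), 2), dtype=float)
    for i, line in enumerate(data_lines):
        parts = line.split("\t") if "\t" in line else line.split()
        try:
            if len(parts) != 2:
                raise ValueError(f"expected 2 columns, found {len(parts)}")
            values[i, 0] = float(parts[0])
            values[i, 1] = float(parts[1])
        except ValueError as exc:
            raise WaveformFormatError(
                f"{path}: cannot parse data line {first_data_lineno + i}: {line!r} ({exc})"
            ) from exc

    kwargs = {}
    for key, conv in _META_KEYS.items():
        if key in meta_raw:
            try:
                kwargs[key] = conv(meta_raw[key])
            except ValueError as exc:
                raise WaveformFormatError(f"{path}: bad metadata value for {key!r}: {exc}") from exc
    meta = ScanMeta(**kwargs)
    if meta.role == "sample" and meta.thickness_mm is None:
        raise WaveformFormatError(f"{path}: sample scan lacks mandatory thickness_mm")
    try:
        return Waveform(values[:, 0], values[:, 1], meta)
    except WaveformFormatError as exc:
        raise WaveformFormatError(f"{path}: {exc}") from exc


def write_manifest(records: pd.DataFrame, path) -> Path:
    """Write a study manifest as a tab-separated table with canonical columns."""
    path = Path(path)
    df = records.reindex(columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_manifest(path) -> pd.DataFrame:
    """Read a study manifest, returning rows sorted by (temperature, replicate, time).

    Ground-truth fraction columns are optional and come back as NaN when the
    manifest describes real data.  Duplicate (sample, time) pairs are an
    error: sequential acquisition can never measure one sample twice at the
    same study time.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = {"file", "role", "temperature_C", "time_h"} - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: manifest lacks required columns {sorted(missing)}")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    samples = df[df["role"] == "sample"]
    dup_keys = samples.duplicated(subset=["temperature_C", "replicate", "time_h"])
    if dup_keys.any():
        bad = samples[dup_keys].iloc[0]
        raise ManifestError(
            f"{path}: duplicate sample row (temperature {bad['temperature_C']}, "
            f"replicate {bad['replicate']}, t = {bad['time_h']} h)"
        )
    df = df.sort_values(["temperature_C", "replicate", "time_h"], kind="stable").reset_index(drop=True)
    logger.info("read manifest %s: %d rows", path, len(df))
    return df[MANIFEST_COLUMNS]


def load_config(path) -> dict:
    """Load a nested key/value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def setup_logging(verbose: bool = False, quiet: bool = False, logfile=None) -> None:
    """Configure timestamped logging to console and, optionally, a file."""
    level = logging.DEBUG if verbose else (logging.WARNING if quiet else logging.INFO)
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
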