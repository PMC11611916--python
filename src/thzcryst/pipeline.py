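"""End-to-end orchestration: simulate → references → extract → fit → monitor.

A single declarative RunConfig drives the whole run.  Stage outputs are
files, not in-memory handoffs, so each stage is independently re-runnable
and testable — the studies themselves are long (days) and analyzed offline,
so a batch, file-centric design fits the workflow.  Rerunning with an
identical configuration and seed reproduces byte-identical result tables;
no stage consumes wall-clock time or filesystem ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics_monitor as km
from .optics import extract_optical_constants
from .spectral_fit import ReferenceModel, fit_crystallinity, fit_reference
from .synthetic_study import (
    KineticsParams,
    PulseParams,
    StudyRefs,
    generate_study,
    synthesize_waveform_pair,
)
from .waveform_io import ScanMeta, logger, read_manifest, read_waveform


class ConfigError(ValueError):
    """Invalid or unknown run-configuration keys/values."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _from_mapping(cls, mapping: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {context!r}")
    coerced = {}
    for f in fields(cls):
        if f.name in mapping:
            v = mapping[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {context!r}: {exc}") from exc


@dataclass(frozen=True)
class PreprocessConfig:
    head_ps: float = 5.0
    tukey_alpha: float = 0.1
    pad_factor: int = 4


@dataclass(frozen=True)
class BandConfig:
    analysis_THz: tuple = (0.3, 2.0)
    fit_THz: tuple = (0.5, 1.8)


@dataclass(frozen=True)
class MonitorConfig:
    keep_every: int = 4
    smooth_window: int = 5
    plots: bool = False


@dataclass(frozen=True)
class StageToggles:
    simulate: bool = True
    references: bool = True
    extract: bool = True
    fit: bool = True
    monitor: bool = True


@dataclass(frozen=True)
class PathConfig:
    study_dir: str = "study"
    out_dir: str = "results"


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run; unknown keys rejected."""

    seed: int = 0
    overwrite: bool = True
    reference_thickness_mm: float = 1.3
    study: KineticsParams = field(default_factory=KineticsParams)
    pulse: PulseParams = field(default_factory=PulseParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    monitor: MonitorConfig = field(default_factory=MonitorConfig)
    stages: StageToggles = field(default_factory=StageToggles)
    paths: PathConfig = field(default_factory=PathConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {
            "study": KineticsParams,
            "pulse": PulseParams,
            "preprocess": PreprocessConfig,
            "bands": BandConfig,
            "monitor": MonitorConfig,
            "stages": StageToggles,
            "paths": PathConfig,
        }
        known_top = {"seed", "overwrite", "reference_thickness_mm", *sections}
        unknown = set(d) - known_top
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        kwargs = {}
        for key in ("seed", "overwrite", "reference_thickness_mm"):
            if key in d:
                kwargs[key] = d[key]
        for name, section_cls in sections.items():
            if name in d:
                if not isinstance(d[name], dict):
                    raise ConfigError(f"section {name!r} must be a mapping")
                kwargs[name] = _from_mapping(section_cls, d[name], name)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _noiseless(pulse: PulseParams) -> PulseParams:
    return dataclasses.replace(pulse, noise_std_au=0.0)


def build_reference_models(config: RunConfig) -> tuple[ReferenceModel, ReferenceModel]:
    """Measure synthetic pure-form tablets and fit their reference models.

    Mirrors the experimental protocol of recording pure α- and β-form
    tablets before the aging study; the synthetic tablets are noiseless so
    the fitted models characterize the forms, not one noise draw.
    """
    refs = StudyRefs()
    pulse = _noiseless(config.pulse)
    d = config.reference_thickness_mm
    out = []
    for form, model in (("alpha", refs.ref_alpha), ("beta", refs.ref_beta)):
        n0 = refs.form_n[form]
        ref_wf, smp_wf = synthesize_waveform_pair(
            n0, model.evaluate, d, pulse, meta=ScanMeta(sample_id=f"pure_{form}")
        )
        oc = extract_optical_constants(
            smp_wf, ref_wf, band_THz=config.bands.analysis_THz,
            head_ps=config.preprocess.head_ps, tukey_alpha=config.preprocess.tukey_alpha,
            pad_factor=config.preprocess.pad_factor,
        )
        out.append(fit_reference(oc.absorption_spectrum(), form, band_THz=config.bands.fit_THz))
    return out[0], out[1]


def _select_evaluated(manifest: pd.DataFrame, keep_every: int) -> pd.DataFrame:
    """Keep every k-th acquisition cycle, per the study's evaluation protocol."""
    times = np.sort(manifest.loc[manifest.role == "sample", "time_h"].unique())
    kept = set(times[::keep_every])
    return manifest[manifest["time_h"].isin(kept) | (manifest.role == "reference")]


def extract_study(manifest: pd.DataFrame, study_dir, config: RunConfig) -> pd.DataFrame:
    """Optical constants for every evaluated sample scan (long table)."""
    study_dir = Path(study_dir)
    refs = manifest[manifest.role == "reference"]
    ref_lookup = {
        (row.temperature_C, round(row.time_h, 6)): row.file for row in refs.itertuples()
    }
    chunks = []
    samples = manifest[manifest.role == "sample"]
    for row in samples.itertuples():
        key = (row.temperature_C, round(row.time_h, 6))
        if key not in ref_lookup:
            raise PipelineError("extract", f"no reference scan for {row.file}")
        smp = read_waveform(study_dir / row.file)
        ref = read_waveform(study_dir / ref_lookup[key])
        oc = extract_optical_constants(
            smp, ref, band_THz=config.bands.analysis_THz,
            head_ps=config.preprocess.head_ps, tukey_alpha=config.preprocess.tukey_alpha,
            pad_factor=config.preprocess.pad_factor,
        )
        chunks.append(
            pd.DataFrame(
                {
                    "sample_id": smp.meta.sample_id,
                    "time_h": row.time_h,
                    "temperature_C": row.temperature_C,
                    "freq_THz": oc.freq_THz,
                    "n": oc.n,
                    "alpha_cm1": oc.alpha_cm1,
                }
            )
        )
    return pd.concat(chunks, ignore_index=True)


def fit_study(optics_table: pd.DataFrame, ref_alpha, ref_beta, config: RunConfig):
    """Crystallinity fits for every scan in an optics long table."""
    from .optics import AbsorptionSpectrum

    fits = []
    for (sample_id, time_h, temp), grp in optics_table.groupby(
        ["sample_id", "time_h", "temperature_C"], sort=True
    ):
        spec = AbsorptionSpectrum(
            grp["freq_THz"].to_numpy(), grp["alpha_cm1"].to_numpy(),
            config.bands.analysis_THz,
            ScanMeta(sample_id=sample_id, temperature_C=temp, time_h=time_h),
        )
        fits.append(fit_crystallinity(spec, ref_alpha, ref_beta, band_THz=config.bands.fit_THz))
    fits.sort(key=lambda f: (f.temperature_C, f.sample_id, f.time_h))
    return fits


def run_all(config: RunConfig, base_dir=".") -> dict:
    """Execute all enabled stages; returns (and writes) the run report."""
    base = Path(base_dir)
    study_dir = base / config.paths.study_dir
    out_dir = base / config.paths.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    report: dict = {"config_sha256": config.digest(), "seed": config.seed}

    def _register(path: Path) -> None:
        artifacts.append(str(path.relative_to(base)))

    if config.stages.simulate:
        try:
            generate_study(
                kinetics=config.study, pulse=config.pulse, out_dir=study_dir,
                seed=config.seed, overwrite=config.overwrite,
            )
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        _register(study_dir / "manifest.tsv")

    models_dir = out_dir / "models"
    if config.stages.references:
        try:
            ref_alpha, ref_beta = build_reference_models(config)
        except Exception as exc:
            raise PipelineError("references", str(exc)) from exc
        models_dir.mkdir(exist_ok=True)
        for m in (ref_alpha, ref_beta):
            _register(m.save(models_dir / f"reference_{m.form}.json"))

    if config.stages.extract:
        try:
            manifest = read_manifest(study_dir / "manifest.tsv")
            evaluated = _select_evaluated(manifest, config.monitor.keep_every)
            optics_table = extract_study(evaluated, study_dir, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("extract", str(exc)) from exc
        optics_path = out_dir / "optics.tsv"
        optics_table.to_csv(optics_path, sep="\t", index=False, float_format="%.9g")
        _register(optics_path)

    if config.stages.fit:
        try:
            optics_table = pd.read_csv(out_dir / "optics.tsv", sep="\t")
            ref_alpha = ReferenceModel.load(models_dir / "reference_alpha.json")
            ref_beta = ReferenceModel.load(models_dir / "reference_beta.json")
            fits = fit_study(optics_table, ref_alpha, ref_beta, config)
        except Exception as exc:
            raise PipelineError("fit", str(exc)) from exc
        fits_path = out_dir / "fits.tsv"
        km.fits_to_frame(fits).to_csv(fits_path, sep="\t", index=False, float_format="%.9g")
        _register(fits_path)

    if config.stages.monitor:
        try:
            fits = km.frame_to_fits(pd.read_csv(out_dir / "fits.tsv", sep="\t"))
            series = km.build_series(fits)
            peak_times = {}
            aggregates = []
            for temp in sorted({s.temperature_C for s in series}):
                group = [s for s in series if s.temperature_C == temp]
                agg = km.aggregate_replicates(group)
                aggregates.append(agg)
                agg_path = out_dir / f"aggregate_T{temp:g}C.tsv"
                agg.to_frame().to_csv(agg_path, sep="\t", index=False, float_format="%.9g")
                _register(agg_path)
                try:
                    peak_times[f"{temp:g}"] = km.peak_time(
                        agg, "B", smooth_window=config.monitor.smooth_window
                    )
                except ValueError as exc:  # series too short or featureless
                    logger.warning("no B-peak estimate at %g °C: %s", temp, exc)
                    peak_times[f"{temp:g}"] = None
            if config.monitor.plots:
                _register(km.plot_aggregates(aggregates, out_dir / "kinetics.png"))
            report["B_peak_time_h_by_temperature"] = peak_times
        except Exception as exc:
            raise PipelineError("monitor", str(exc)) from exc

    report["artifacts"] = artifacts
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d artifacts, report at %s", len(artifacts), report_path)
    return report
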