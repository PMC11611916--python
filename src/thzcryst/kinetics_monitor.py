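"""Time-series assembly and replicate aggregation of crystallinity fits.

Groups per-scan (A, B) fits into per-sample series, applies the study's
every-kth decimation, aggregates replicates stored at the same temperature
into mean ± standard deviation bands, and estimates the time at which the
metastable-form coefficient B peaks — the observable that orders storage
temperatures by crystallization speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class KineticsSeries:
    """A(t) and B(t) for one sample."""

    sample_id: str
    temperature_C: float
    times_h: np.ndarray
    A_values: np.ndarray
    B_values: np.ndarray

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.A_values = np.asarray(self.A_values, dtype=float)
        self.B_values = np.asarray(self.B_values, dtype=float)
        if not (len(self.times_h) == len(self.A_values) == len(self.B_values)):
            raise ValueError("times, A and B must have equal lengths")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError(f"series {self.sample_id}: times must be strictly increasing")


@dataclass
class AggregateSeries:
    """Replicate mean ± population standard deviation per temperature."""

    temperature_C: float
    times_h: np.ndarray
    A_mean: np.ndarray
    A_std: np.ndarray
    B_mean: np.ndarray
    B_std: np.ndarray
    n_replicates: int

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if np.any(self.A_std < 0) or np.any(self.B_std < 0):
            raise ValueError("standard deviations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "A_mean": self.A_mean,
                "A_std": self.A_std,
                "B_mean": self.B_mean,
                "B_std": self.B_std,
            }
        )


def build_series(fits) -> list[KineticsSeries]:
    """Group crystallinity fits by sample and sort each group by time."""
    by_sample: dict[str, list] = {}
    for f in fits:
        by_sample.setdefault(f.sample_id, []).append(f)
    out = []
    for sample_id, group in by_sample.items():
        group.sort(key=lambda f: f.time_h)
        times = np.array([f.time_h for f in group])
        if len(np.unique(times)) != len(times):
            dup = times[np.nonzero(np.diff(times) == 0)[0][0]]
            raise ValueError(f"sample {sample_id!r}: duplicate fits at t = {dup} h")
        out.append(
            KineticsSeries(
                sample_id=sample_id,
                temperature_C=group[0].temperature_C,
                times_h=times,
                A_values=np.array([f.A for f in group]),
                B_values=np.array([f.B for f in group]),
            )
        )
    out.sort(key=lambda s: (s.temperature_C, s.sample_id))
    return out


def decimate(series: KineticsSeries, keep_every: int = 4) -> KineticsSeries:
    """Keep every ``keep_every``-th point (indices 0, k, 2k, …).

    At the study cadence of 3.5 min, the default k = 4 yields one evaluated
    acquisition every 14 min.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    sl = slice(None, None, keep_every)
    return KineticsSeries(
        sample_id=series.sample_id,
        temperature_C=series.temperature_C,
        times_h=series.times_h[sl],
        A_values=series.A_values[sl],
        B_values=series.B_values[sl],
    )


def aggregate_replicates(series_list, time_tol_min: float = 1.0) -> AggregateSeries:
    """Pointwise mean and population std of A and B across replicates.

    All series must share the storage temperature, and their time grids must
    agree within ``time_tol_min`` (sequential acquisition staggers samples by
    seconds, not minutes).  No interpolation is performed.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("need at least one series to aggregate")
    first = series_list[0]
    tol_h = time_tol_min / 60.0
    for s in series_list[1:]:
        if s.temperature_C != first.temperature_C:
            raise ValueError(
                f"cannot aggregate across temperatures ({s.temperature_C} != {first.temperature_C})"
            )
        if len(s.times_h) != len(first.times_h) or np.any(np.abs(s.times_h - first.times_h) > tol_h):
            raise ValueError(
                f"replicate {s.sample_id!r}: time grid differs from {first.sample_id!r} "
                f"by more than {time_tol_min} min"
            )
    A = np.vstack([s.A_values for s in series_list])
    B = np.vstack([s.B_values for s in series_list])
    return AggregateSeries(
        temperature_C=first.temperature_C,
        times_h=first.times_h.copy(),
        A_mean=A.mean(axis=0),
        A_std=A.std(axis=0, ddof=0),
        B_mean=B.mean(axis=0),
        B_std=B.std(axis=0, ddof=0),
        n_replicates=len(series_list),
    )


def peak_time(series, coefficient: str = "B", smooth_window: int = 5) -> float:
    """Time at which the (smoothed) coefficient series is maximal.

    A centered moving average of ``smooth_window`` points (edges handled by
    repeating the boundary value) makes the estimate robust to acquisition
    noise; ties are broken toward the earliest time.  Accepts a
    KineticsSeries or an AggregateSeries (which uses the replicate mean).
    """
    if coefficient not in ("A", "B"):
        raise ValueError("coefficient must be 'A' or 'B'")
    if isinstance(series, AggregateSeries):
        values = series.A_mean if coefficient == "A" else series.B_mean
    else:
        values = series.A_values if coefficient == "A" else series.B_values
    times = series.times_h
    if len(values) < smooth_window:
        raise ValueError(f"need at least {smooth_window} points to locate a peak")
    if np.all(values == 0):
        raise ValueError("all-zero series has no peak")
    from scipy.ndimage import uniform_filter1d

    smoothed = uniform_filter1d(values.astype(float), size=smooth_window, mode="nearest")
    return float(times[int(np.argmax(smoothed))])


def fits_to_frame(fits) -> pd.DataFrame:
    """Tabulate crystallinity fits for on-disk result tables."""
    return pd.DataFrame(
        {
            "sample_id": [f.sample_id for f in fits],
            "temperature_C": [f.temperature_C for f in fits],
            "time_h": [f.time_h for f in fits],
            "A": [f.A for f in fits],
            "B": [f.B for f in fits],
            "bg_c0": [f.background[0] for f in fits],
            "bg_c1": [f.background[1] for f in fits],
            "bg_c2": [f.background[2] for f in fits],
            "residual_rms_cm1": [f.residual_rms_cm1 for f in fits],
        }
    )


def frame_to_fits(df: pd.DataFrame):
    """Inverse of :func:`fits_to_frame` (for table-driven CLI stages)."""
    from .spectral_fit import CrystallinityFit

    return [
        CrystallinityFit(
            A=row.A,
            B=row.B,
            background=(row.bg_c0, row.bg_c1, row.bg_c2),
            residual_rms_cm1=row.residual_rms_cm1,
            sample_id=row.sample_id,
            temperature_C=row.temperature_C,
            time_h=row.time_h,
        )
        for row in df.itertuples()
    ]


def plot_aggregates(aggregates, out_path) -> Path:
    """One panel per temperature: A and B vs. time with ±1 std bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    aggregates = sorted(aggregates, key=lambda a: a.temperature_C)
    fig, axes = plt.subplots(1, len(aggregates), figsize=(4.5 * len(aggregates), 3.5), squeeze=False)
    for ax, agg in zip(axes[0], aggregates):
        for name, mean, std, color in (
            ("A (α-form)", agg.A_mean, agg.A_std, "tab:red"),
            ("B (β-form)", agg.B_mean, agg.B_std, "tab:blue"),
        ):
            ax.plot(agg.times_h, mean, color=color, label=name)
            ax.fill_between(agg.times_h, mean - std, mean + std, color=color, alpha=0.2)
        ax.set_title(f"{agg.temperature_C:g} °C ({agg.n_replicates} replicates)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("fit coefficient")
        ax.legend()
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
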