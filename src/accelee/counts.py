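"""ActiGraph-style activity counts from raw acceleration.

Implements the open-source replication of the ActiGraph counts algorithm
published by Brønd, Andersen & Arvidsson (2017) — the algorithm behind the R
``activityCounts`` library.  The chain is:

1. resample each axis to 30 Hz (linear interpolation; exact-30 Hz input
   passes through untouched);
2. band-pass filter with the published 20th-order IIR replica of the
   device's analog filter (≈0.29–1.63 Hz passband);
3. decimate the filtered signal to 10 Hz;
4. clip at the ±2.13 g ceiling, rectify, zero everything below the 0.068 g
   dead-band, and quantize to 1/0.0164 g ADC units (floor);
5. sum 10 consecutive 10-Hz samples into one count value per second.

Per-second counts are then combined into the vector magnitude and averaged
into the per-minute / per-10-s epoch values the MET equations consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import lfilter, lfilter_zi

from .errors import DataError
from .signal_io import RawAccelSignal

# Band-pass filter coefficients transcribed from the open-source ActiGraph
# count replication (Brønd et al. 2017; same constants as the R
# "activityCounts" implementation).  Order matters: B is scaled by GAIN
# before filtering.
BP_B = np.array([
    0.049109, -0.12284, 0.14356, -0.11269, 0.053804, -0.02023,
    0.0063778, 0.018513, -0.038154, 0.048727, -0.052577, 0.047847,
    -0.046015, 0.036283, -0.012977, -0.0046262, 0.012835, -0.0093762,
    0.0034485, -0.00080972, -0.00019623,
])
BP_A = np.array([
    1.0, -4.1637, 7.5712, -7.9805, 5.385, -2.4636, 0.89238, 0.06361,
    -1.3481, 2.4734, -2.9257, 2.9298, -2.7816, 2.4777, -1.6847,
    0.46483, 0.46565, -0.67312, 0.4162, -0.13832, 0.019852,
])
GAIN = 0.965            # pre-filter scale applied to B
DEADBAND_G = 0.068      # rectified values below this contribute nothing
PEAK_G = 2.13           # clip ceiling of the filtered signal, g
ADC_RESOLUTION_G = 0.0164  # quantization step, g per count unit
TARGET_FS_HZ = 30       # filter is defined at 30 Hz
DECIMATED_FS_HZ = 10    # post-filter rate; 10 samples summed per second

#: Upper bound on a single per-second count value (clip ceiling, quantized,
#: summed over one second of 10-Hz samples).
MAX_COUNTS_PER_SECOND = int(PEAK_G / ADC_RESOLUTION_G) * DECIMATED_FS_HZ


@dataclass
class CountsSeries:
    """Per-second activity counts for one axis (or the vector magnitude)."""

    record_id: str
    axis: str  # "x" | "y" | "z" | "vm"
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise DataError(f"{self.record_id}/{self.axis}: negative counts")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class EpochSummary:
    """Per-record epoch averages feeding the MET equations.

    ``ac_vt_cpm`` / ``ac_vm_cpm`` are counts per minute on the designated
    vertical axis and on the vector magnitude; ``ac_vt_c10s`` is the vertical
    axis in counts per 10 s (the input unit of the Crouter equation).
    """

    record_id: str
    ac_vt_cpm: float
    ac_vm_cpm: float
    ac_vt_c10s: float

    def __post_init__(self) -> None:
        for name in ("ac_vt_cpm", "ac_vm_cpm", "ac_vt_c10s"):
            if getattr(self, name) < 0:
                raise DataError(f"{self.record_id}: {name} negative")


def _resample_to_30hz(t: np.ndarray, x: np.ndarray, fs: float) -> np.ndarray:
    """Linear-interpolate one axis onto a uniform 30 Hz grid.

    Input already on a uniform 30 Hz grid is returned as-is so that
    native-rate recordings are bit-exact through this step.
    """
    if len(t) < 2:
        raise DataError("cannot resample fewer than 2 samples")
    dt = np.diff(t)
    if abs(fs - TARGET_FS_HZ) < 1e-9 and np.allclose(dt, 1.0 / TARGET_FS_HZ, rtol=0, atol=1e-9):
        return x
    n_out = int(np.floor((t[-1] - t[0]) * TARGET_FS_HZ)) + 1
    t_new = t[0] + np.arange(n_out) / TARGET_FS_HZ
    return np.interp(t_new, t, x)


def _counts_from_30hz(x30: np.ndarray) -> np.ndarray:
    """Filter → decimate → clip/rectify/dead-band/quantize → per-second sums."""
    b = BP_B * GAIN
    # Steady-state initial conditions for the first sample's value: a constant
    # (gravity-only) trace then yields its steady-state band-pass response
    # (~0) rather than a power-on step transient.
    zi = lfilter_zi(b, BP_A) * x30[0]
    filtered, _ = lfilter(b, BP_A, x30, zi=zi)
    f10 = filtered[::3]                       # 30 Hz -> 10 Hz
    f10 = np.clip(f10, -PEAK_G, PEAK_G)
    rect = np.abs(f10)
    rect[rect < DEADBAND_G] = 0.0
    units = np.floor(rect / ADC_RESOLUTION_G)
    n_sec = len(units) // DECIMATED_FS_HZ     # partial trailing second discarded
    if n_sec == 0:
        raise DataError("signal shorter than 1 s after resampling")
    return units[: n_sec * DECIMATED_FS_HZ].reshape(n_sec, DECIMATED_FS_HZ).sum(axis=1).astype(np.int64)


def counts_per_second(signal: RawAccelSignal, axis: str,
                      trim_lead_seconds: float = 0.0) -> CountsSeries:
    """Activity counts per second on one axis of a raw signal.

    ``trim_lead_seconds`` drops an unstable lead-in (for raw dumps that still
    contain the warm-up minute); the default assumes input is already the
    recorded bout.
    """
    if signal.sample_rate_hz <= 0:
        raise DataError(f"{signal.record_id}: sample rate must be > 0")
    t, x = signal.timestamps, signal.axis(axis)
    if trim_lead_seconds > 0:
        keep = t >= t[0] + trim_lead_seconds
        t, x = t[keep], x[keep]
    if len(t) < 2 or (t[-1] - t[0]) + 1.0 / signal.sample_rate_hz < 1.0:
        raise DataError(f"{signal.record_id}: signal shorter than 1 s")
    x30 = _resample_to_30hz(t, x, signal.sample_rate_hz)
    return CountsSeries(signal.record_id, axis, _counts_from_30hz(x30))


def triaxial_counts(signal: RawAccelSignal,
                    trim_lead_seconds: float = 0.0) -> dict[str, CountsSeries]:
    """Counts per second for x, y, z plus their vector magnitude."""
    out = {ax: counts_per_second(signal, ax, trim_lead_seconds) for ax in ("x", "y", "z")}
    out["vm"] = vector_magnitude_counts(out["x"], out["y"], out["z"])
    return out


def vector_magnitude_counts(cx: CountsSeries, cy: CountsSeries,
                            cz: CountsSeries) -> CountsSeries:
    """Per-second Euclidean norm of the three axes' counts."""
    if not (len(cx) == len(cy) == len(cz)):
        raise DataError(
            f"{cx.record_id}: axis count lengths differ "
            f"({len(cx)}, {len(cy)}, {len(cz)})"
        )
    if not (cx.record_id == cy.record_id == cz.record_id):
        raise DataError("vector magnitude requires counts from the same record")
    vm = np.sqrt(cx.counts.astype(float) ** 2 + cy.counts ** 2 + cz.counts ** 2)
    return CountsSeries(cx.record_id, "vm", vm)


def epoch_average(counts: CountsSeries, epoch: str = "per_min",
                  bout_minutes: float = 2.0) -> float:
    """Average counts per epoch over a bout.

    ``per_min`` divides the bout's total counts by its minutes (the study's
    ÷2 for 2-min bouts); ``per_10s`` divides by the number of 10-s windows
    (÷12 for 2-min bouts).
    """
    n_needed = int(round(bout_minutes * 60))
    if n_needed > len(counts):
        raise DataError(
            f"{counts.record_id}: bout of {bout_minutes} min needs {n_needed} s, "
            f"series has {len(counts)} s"
        )
    total = float(np.sum(counts.counts[:n_needed]))
    if epoch == "per_min":
        return total / bout_minutes
    if epoch == "per_10s":
        return total / (bout_minutes * 6)
    raise DataError(f"unknown epoch {epoch!r}; expected 'per_min' or 'per_10s'")


def epoch_summary(signal: RawAccelSignal, vertical_axis: str,
                  bout_minutes: float = 2.0,
                  trim_lead_seconds: float = 0.0) -> EpochSummary:
    """Full raw-signal → epoch reduction for one record."""
    per_sec = triaxial_counts(signal, trim_lead_seconds)
    vt = per_sec[vertical_axis]
    return EpochSummary(
        record_id=signal.record_id,
        ac_vt_cpm=epoch_average(vt, "per_min", bout_minutes),
        ac_vm_cpm=epoch_average(per_sec["vm"], "per_min", bout_minutes),
        ac_vt_c10s=epoch_average(vt, "per_10s", bout_minutes),
    )


def write_counts_csv(series: dict[str, CountsSeries], path: str | Path) -> Path:
    """Per-second counts CSV: record_id, second_index, x, y, z, vm."""
    path = Path(path)
    n = len(series["x"])
    df = pd.DataFrame({
        "record_id": series["x"].record_id,
        "second_index": np.arange(n),
        "x": series["x"].counts, "y": series["y"].counts, "z": series["z"].counts,
        "vm": series["vm"].counts,
    })
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\r\n")
    return path


def write_epoch_summary_csv(summaries: Iterable[EpochSummary], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([s.__dict__ for s in summaries])
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\r\n")
    return path
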