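"""Raw accelerometer CSV I/O and study-manifest bookkeeping.

A *record* is one sensor worn by one participant during one treadmill bout.
Raw records are plain CSV files with a time column plus x/y/z acceleration in
g; the manifest maps record IDs to participant, device, placement,
configuration and treadmill speed.  Timestamps are stored as elapsed seconds
from the start of the record; an absolute start time, when present in the
file, is kept as metadata only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError

#: Treadmill speeds of the study design, km/h.
STUDY_SPEEDS_KMH: tuple[float, ...] = (1.4, 2.9, 4.3, 5.0, 6.0, 6.5, 7.0, 8.0, 9.0, 10.0)

#: Record IDs flagged as invalid monitor data (initialization errors / device
#: malfunction) in the reference data collection for this design.  The list is
#: configuration, not behaviour: nothing in the pipeline treats these IDs
#: specially unless a caller passes them to :func:`apply_exclusions`.
DEFAULT_EXCLUDED_RECORDS: tuple[str, ...] = ("t2221", "t221", "t2130", "t3127")

PLACEMENTS = ("wrist", "thigh")
DEVICES = ("actigraph", "sensorid")

#: Factory dynamic range per device family, g.
DEVICE_RANGE_G = {"actigraph": 8.0, "sensorid": 16.0}


@dataclass(frozen=True)
class CsvDialect:
    """Layout of a raw accelerometer CSV.

    ``time_format`` is either ``"elapsed"`` (numeric seconds from record
    start) or ``"iso8601"`` (absolute timestamps, converted to elapsed
    seconds on read).  The default matches a comma-separated RAW export with
    a single header line.
    """

    time_col: str = "time"
    x_col: str = "x"
    y_col: str = "y"
    z_col: str = "z"
    delimiter: str = ","
    time_format: str = "elapsed"  # or "iso8601"

    def axis_cols(self) -> dict[str, str]:
        return {"x": self.x_col, "y": self.y_col, "z": self.z_col}


DEFAULT_DIALECT = CsvDialect()


@dataclass
class RawAccelSignal:
    """One record's tri-axial acceleration trace in g.

    ``timestamps`` are elapsed seconds, strictly increasing; the three axis
    arrays are the same length as ``timestamps``.
    """

    record_id: str
    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float
    device: str = "actigraph"
    dynamic_range_g: float = 8.0
    start_time: str | None = None  # absolute wall clock of first sample, metadata only

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.timestamps)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise DataError(
                f"{self.record_id}: axis lengths "
                f"({len(self.ax)}, {len(self.ay)}, {len(self.az)}) "
                f"do not match {n} timestamps"
            )
        if self.sample_rate_hz <= 0:
            raise DataError(f"{self.record_id}: sample_rate_hz must be > 0")
        for name, arr in (("time", self.timestamps), ("x", self.ax), ("y", self.ay), ("z", self.az)):
            if not np.all(np.isfinite(arr)):
                idx = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise DataError(f"{self.record_id}: non-finite {name} value at row {idx}")
        if n > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                idx = int(np.flatnonzero(dt <= 0)[0]) + 1
                raise DataError(
                    f"{self.record_id}: timestamps not strictly increasing at row {idx}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        """Recorded span plus one nominal sample interval (duration covered)."""
        if self.n_samples == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.sample_rate_hz

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"x": self.ax, "y": self.ay, "z": self.az}[name]
        except KeyError:
            raise DataError(f"unknown axis {name!r}; expected one of x, y, z") from None


def read_raw_csv(
    path: str | Path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    *,
    record_id: str | None = None,
    sample_rate_hz: float | None = None,
    device: str = "actigraph",
    dynamic_range_g: float | None = None,
) -> RawAccelSignal:
    """Read one raw accelerometer CSV into a validated :class:`RawAccelSignal`.

    Rows with unparseable values raise :class:`FormatError` (naming the column
    and row); they are never silently dropped.  When ``sample_rate_hz`` is not
    given it is inferred from the median timestamp interval.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    needed = {dialect.time_col: "time", **{v: k for k, v in dialect.axis_cols().items()}}
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")

    start_time = None
    if dialect.time_format == "iso8601":
        t_abs = pd.to_datetime(df[dialect.time_col], errors="coerce", format="ISO8601")
        if t_abs.isna().any():
            row = int(t_abs.isna().idxmax())
            raise FormatError(f"{path.name}: unparseable timestamp in column "
                              f"{dialect.time_col!r} at row {row}")
        start_time = t_abs.iloc[0].isoformat()
        t = (t_abs - t_abs.iloc[0]).dt.total_seconds().to_numpy()
    elif dialect.time_format == "elapsed":
        t = _numeric(df, dialect.time_col, path.name)
    else:
        raise FormatError(f"unknown time_format {dialect.time_format!r}")

    ax = _numeric(df, dialect.x_col, path.name)
    ay = _numeric(df, dialect.y_col, path.name)
    az = _numeric(df, dialect.z_col, path.name)

    if sample_rate_hz is None:
        if len(t) < 2:
            raise DataError(f"{path.name}: cannot infer sample rate from {len(t)} sample(s)")
        sample_rate_hz = float(1.0 / np.median(np.diff(t)))
    if dynamic_range_g is None:
        dynamic_range_g = DEVICE_RANGE_G.get(device, 8.0)
    return RawAccelSignal(
        record_id=record_id or path.stem,
        timestamps=t, ax=ax, ay=ay, az=az,
        sample_rate_hz=sample_rate_hz,
        device=device, dynamic_range_g=dynamic_range_g,
        start_time=start_time,
    )


def _numeric(df: pd.DataFrame, col: str, fname: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise FormatError(f"{fname}: unparseable value in column {col!r} at row {row}")
    return vals.to_numpy(dtype=float)


def write_raw_csv(signal: RawAccelSignal, path: str | Path,
                  dialect: CsvDialect = DEFAULT_DIALECT) -> Path:
    """Write a signal back to CSV in the given dialect (elapsed seconds only)."""
    path = Path(path)
    df = pd.DataFrame({
        dialect.time_col: signal.timestamps,
        dialect.x_col: signal.ax,
        dialect.y_col: signal.ay,
        dialect.z_col: signal.az,
    })
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.9f", lineterminator="\r\n")
    return path


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestRecord:
    record_id: str
    participant_id: str
    device: str            # "actigraph" | "sensorid"
    placement: str         # "wrist" | "thigh"
    configuration: int     # 1 | 2
    speed_kmh: float
    duration_min: float | None = None


@dataclass
class StudyManifest:
    """Ordered collection of manifest records with unique IDs."""

    records: list[ManifestRecord] = field(default_factory=list)
    valid_speeds: tuple[float, ...] = STUDY_SPEEDS_KMH

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DataError(f"duplicate record_id {dup!r} in manifest")
        if self.valid_speeds is not None:
            allowed = set(self.valid_speeds)
            for r in self.records:
                if r.speed_kmh not in allowed:
                    raise DataError(
                        f"{r.record_id}: speed {r.speed_kmh} km/h not in study speed set"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def apply_exclusions(manifest: StudyManifest, excluded_ids: Iterable[str]) -> StudyManifest:
    """Drop the listed record IDs from the manifest, preserving order.

    IDs absent from the manifest raise a warning, not an error (the exclusion
    list may be shared across study subsets).  Idempotent.
    """
    excluded = list(excluded_ids)
    present = set(manifest.record_ids)
    missing = [i for i in excluded if i not in present]
    if missing:
        warnings.warn(
            f"exclusion list contains {len(missing)} ID(s) not in manifest: "
            + ", ".join(missing),
            stacklevel=2,
        )
    drop = set(excluded)
    kept = [r for r in manifest.records if r.record_id not in drop]
    return StudyManifest(records=kept, valid_speeds=manifest.valid_speeds)


def total_minutes(manifest: StudyManifest) -> float:
    """Sum of recorded minutes across the manifest."""
    total = 0.0
    for r in manifest:
        if r.duration_min is None or (isinstance(r.duration_min, float) and np.isnan(r.duration_min)):
            raise DataError(f"{r.record_id}: duration_min missing")
        total += float(r.duration_min)
    return total


_MANIFEST_COLS = ["record_id", "participant_id", "device", "placement",
                  "configuration", "speed_kmh", "duration_min"]


def read_manifest(path: str | Path,
                  valid_speeds: Sequence[float] | None = STUDY_SPEEDS_KMH) -> StudyManifest:
    """Read a manifest from CSV (or YAML, by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        rows = raw["records"] if isinstance(raw, dict) else raw
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    for col in _MANIFEST_COLS[:-1]:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing manifest column {col!r}")
    if "duration_min" not in df.columns:
        df["duration_min"] = np.nan
    records = [
        ManifestRecord(
            record_id=str(row.record_id),
            participant_id=str(row.participant_id),
            device=str(row.device),
            placement=str(row.placement),
            configuration=int(row.configuration),
            speed_kmh=float(row.speed_kmh),
            duration_min=None if pd.isna(row.duration_min) else float(row.duration_min),
        )
        for row in df.itertuples(index=False)
    ]
    return StudyManifest(records=records,
                         valid_speeds=tuple(valid_speeds) if valid_speeds is not None else None)


def write_manifest(manifest: StudyManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_frame().to_csv(path, index=False, lineterminator="\r\n")
    return path
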