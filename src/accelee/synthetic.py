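"""Synthetic wearable gait recordings with the study's paired-device design.

The generator emulates treadmill walking/running bouts recorded by co-located
accelerometers: a gravity offset on one axis, a harmonic series at the gait's
step frequency (fundamental + decaying overtones), shared "motion" noise, and
independent device noise.  It reproduces the study layout — 5 participants ×
3 sensors × 2 wearing configurations × 10 speeds, 2-min bouts at 30 Hz —
deterministically from a single study seed.  The goal is controllable
statistical structure for testing the counts → METs → reliability pipeline,
not biomechanically validated gait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .equations import Participant
from .errors import DataError
from .signal_io import (DEVICE_RANGE_G, ManifestRecord, RawAccelSignal,
                        STUDY_SPEEDS_KMH, StudyManifest)

#: Step-frequency map endpoints: fundamental rises linearly with speed and
#: stays inside the count filter's passband.
_SPEED_LO, _SPEED_HI = 1.4, 10.0        # km/h
_STEP_HZ_LO, _STEP_HZ_HI = 1.0, 1.8     # Hz (stride rate; stays in the
                                        # count filter's high-gain band)
_AMP_LO, _AMP_HI = 0.05, 1.2            # g, dominant-axis dynamic amplitude

#: Placement multiplier on dynamic amplitude (wrist moves less than thigh
#: during gait in this model, making the placement contrast weaker than the
#: device contrast).
PLACEMENT_AMPLITUDE = {"thigh": 1.0, "wrist": 0.8}

#: Relative dynamic amplitude per axis (y carries the dominant limb-axis
#: component; gravity sits on z by default).
AXIS_RATIOS = {"x": 0.4, "y": 1.0, "z": 0.6}


@dataclass(frozen=True)
class GaitModel:
    """Parameters of one simulated bout's motion."""

    speed_kmh: float
    step_frequency_hz: float
    amplitude_g: float          # dominant-axis amplitude of the fundamental
    gravity_axis: str = "z"
    noise_sd_g: float = 0.02    # shared motion noise (not device noise)
    harmonics: int = 3

    def __post_init__(self) -> None:
        if self.step_frequency_hz <= 0 or self.amplitude_g < 0:
            raise DataError("step frequency must be > 0 and amplitude >= 0")
        if self.harmonics < 1:
            raise DataError("need at least one harmonic")

    @classmethod
    def for_speed(cls, speed_kmh: float, placement: str = "thigh",
                  subject_scale: float = 1.0, **kwargs) -> "GaitModel":
        """Default speed → gait map: linear step frequency and amplitude."""
        frac = (speed_kmh - _SPEED_LO) / (_SPEED_HI - _SPEED_LO)
        step = _STEP_HZ_LO + frac * (_STEP_HZ_HI - _STEP_HZ_LO)
        amp = (_AMP_LO + frac * (_AMP_HI - _AMP_LO)) * PLACEMENT_AMPLITUDE[placement]
        return cls(speed_kmh=speed_kmh, step_frequency_hz=step,
                   amplitude_g=amp * subject_scale, **kwargs)


@dataclass(frozen=True)
class SensorSpec:
    """One worn sensor: device family and its placement per configuration."""

    index: int                       # 1-based; sensor 1's digit is elided in record IDs
    device: str                      # "actigraph" | "sensorid"
    placement_by_config: dict[int, str]


#: The study's three sensors: a wrist ActiGraph, a thigh ActiGraph, and the
#: low-cost sensor taped next to one of them (wrist in configuration 1,
#: thigh in configuration 2).
DEFAULT_SENSORS: tuple[SensorSpec, ...] = (
    SensorSpec(1, "actigraph", {1: "wrist", 2: "wrist"}),
    SensorSpec(2, "actigraph", {1: "thigh", 2: "thigh"}),
    SensorSpec(3, "sensorid", {1: "wrist", 2: "thigh"}),
)


@dataclass(frozen=True)
class SimDesign:
    """Full-study simulation design (defaults reproduce the 300-record layout)."""

    seed: int
    n_participants: int = 5
    sensors: tuple[SensorSpec, ...] = DEFAULT_SENSORS
    n_configurations: int = 2
    speeds: tuple[float, ...] = STUDY_SPEEDS_KMH
    bout_minutes: float = 2.0
    fs_hz: float = 30.0
    device_noise_sd_g: dict[str, float] = field(
        default_factory=lambda: {"actigraph": 0.005, "sensorid": 0.01})
    subject_scale_sd: float = 0.15   # lognormal sd of per-participant gait amplitude
    motion_noise_sd_g: float = 0.02

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_configurations < 1 or not self.speeds:
            raise DataError("design counts must be positive")
        if self.seed is None:
            raise DataError("a seed is mandatory for reproducibility")


def _rng(*key: int) -> np.random.Generator:
    """Hierarchical RNG: streams keyed by integers are stable under design edits."""
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _harmonic_motion(model: GaitModel, t: np.ndarray,
                     phases: np.ndarray) -> dict[str, np.ndarray]:
    """Deterministic harmonic series per axis (amplitude halves per overtone)."""
    base = np.zeros_like(t)
    for h in range(model.harmonics):
        base += (0.5 ** h) * np.sin(2 * np.pi * (h + 1) * model.step_frequency_hz * t
                                    + phases[h])
    return {ax: model.amplitude_g * ratio * base for ax, ratio in AXIS_RATIOS.items()}


def _assemble(model: GaitModel, t: np.ndarray, motion: dict[str, np.ndarray],
              motion_noise: dict[str, np.ndarray],
              device_noise: dict[str, np.ndarray],
              *, record_id: str, device: str, fs_hz: float,
              dynamic_range_g: float) -> RawAccelSignal:
    axes = {}
    clipped = False
    for ax in ("x", "y", "z"):
        sig = motion[ax] + motion_noise[ax] + device_noise[ax]
        if ax == model.gravity_axis:
            sig = sig + 1.0
        if np.any(np.abs(sig) > dynamic_range_g):
            clipped = True
            sig = np.clip(sig, -dynamic_range_g, dynamic_range_g)
        axes[ax] = sig
    if clipped:
        warnings.warn(f"{record_id}: signal saturated at ±{dynamic_range_g} g; clipped",
                      stacklevel=3)
    return RawAccelSignal(record_id=record_id, timestamps=t,
                          ax=axes["x"], ay=axes["y"], az=axes["z"],
                          sample_rate_hz=fs_hz, device=device,
                          dynamic_range_g=dynamic_range_g)


def simulate_bout(model: GaitModel, duration_min: float = 2.0, fs_hz: float = 30.0,
                  seed: int = 0, *, record_id: str = "sim",
                  device: str = "actigraph",
                  device_noise_sd_g: float = 0.0,
                  dynamic_range_g: float | None = None) -> RawAccelSignal:
    """One simulated bout: gravity + harmonics + motion noise (+ device noise)."""
    if dynamic_range_g is None:
        dynamic_range_g = DEVICE_RANGE_G.get(device, 8.0)
    n = int(round(duration_min * 60 * fs_hz))
    t = np.arange(n) / fs_hz
    rng = _rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=model.harmonics)
    motion = _harmonic_motion(model, t, phases)
    motion_noise = {ax: rng.normal(0, model.noise_sd_g, n) for ax in ("x", "y", "z")}
    dev_rng = _rng(seed, 1)
    device_noise = {ax: (dev_rng.normal(0, device_noise_sd_g, n) if device_noise_sd_g > 0
                         else np.zeros(n)) for ax in ("x", "y", "z")}
    return _assemble(model, t, motion, motion_noise, device_noise,
                     record_id=record_id, device=device, fs_hz=fs_hz,
                     dynamic_range_g=dynamic_range_g)


_MASTER_FS = 120.0  # grid on which shared motion noise is generated for pairs


def simulate_paired_devices(model: GaitModel, noise_a: float, noise_b: float,
                            duration_min: float = 2.0, fs_a: float = 30.0,
                            fs_b: float = 30.0, seed: int = 0,
                            *, record_id_a: str = "sim_a", record_id_b: str = "sim_b",
                            device_a: str = "actigraph", device_b: str = "sensorid",
                            ) -> tuple[RawAccelSignal, RawAccelSignal]:
    """Two co-located sensors sharing one motion realization.

    The harmonic component is evaluated analytically at each device's own
    sample times; shared motion noise is generated once on a dense master
    grid and interpolated, so both devices see the same movement before their
    independent device noise is added.  With equal rates and zero device
    noise the two signals are identical.
    """
    rng = _rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=model.harmonics)
    n_master = int(round(duration_min * 60 * _MASTER_FS)) + 1
    t_master = np.arange(n_master) / _MASTER_FS
    noise_master = {ax: rng.normal(0, model.noise_sd_g, n_master) for ax in ("x", "y", "z")}

    out = []
    for which, (fs, dev_noise, rid, device) in enumerate(
            [(fs_a, noise_a, record_id_a, device_a),
             (fs_b, noise_b, record_id_b, device_b)]):
        n = int(round(duration_min * 60 * fs))
        t = np.arange(n) / fs
        motion = _harmonic_motion(model, t, phases)
        motion_noise = {ax: np.interp(t, t_master, noise_master[ax]) for ax in ("x", "y", "z")}
        dev_rng = _rng(seed, 2 + which)
        device_noise = {ax: (dev_rng.normal(0, dev_noise, n) if dev_noise > 0
                             else np.zeros(n)) for ax in ("x", "y", "z")}
        out.append(_assemble(model, t, motion, motion_noise, device_noise,
                             record_id=rid, device=device, fs_hz=fs,
                             dynamic_range_g=DEVICE_RANGE_G.get(device, 8.0)))
    return out[0], out[1]


def _record_id(participant: int, configuration: int, sensor: SensorSpec,
               speed_index: int) -> str:
    """ID scheme t{p}{c}[{s}]{i}: the first sensor's digit is elided."""
    s = "" if sensor.index == 1 else str(sensor.index)
    return f"t{participant}{configuration}{s}{speed_index}"


def simulate_participants(design: SimDesign) -> list[Participant]:
    """Plausible adult anthropometrics, deterministic from the study seed.

    Ages 20–45 y, body mass 55–90 kg, height 1.55–1.90 m, gender balanced at
    random — healthy-adult ranges for a treadmill protocol.
    """
    rng = _rng(design.seed, 101)
    out = []
    for p in range(1, design.n_participants + 1):
        out.append(Participant(
            participant_id=f"p{p}",
            age=float(np.round(rng.uniform(20, 45), 1)),
            body_mass_kg=float(np.round(rng.uniform(55, 90), 1)),
            height_m=float(np.round(rng.uniform(1.55, 1.90), 2)),
            gender_code=int(rng.integers(1, 3)),
        ))
    return out


def study_manifest(design: SimDesign) -> StudyManifest:
    """Manifest of the full design without generating any signals."""
    records = []
    for p in range(1, design.n_participants + 1):
        for c in range(1, design.n_configurations + 1):
            for sensor in design.sensors:
                for i, speed in enumerate(design.speeds):
                    records.append(ManifestRecord(
                        record_id=_record_id(p, c, sensor, i),
                        participant_id=f"p{p}",
                        device=sensor.device,
                        placement=sensor.placement_by_config[c],
                        configuration=c,
                        speed_kmh=speed,
                        duration_min=design.bout_minutes,
                    ))
    return StudyManifest(records=records, valid_speeds=tuple(design.speeds))


def simulate_study(design: SimDesign
                   ) -> tuple[StudyManifest, list[RawAccelSignal], list[Participant]]:
    """Generate the full study: manifest, one raw signal per record, participants.

    Sensors taped at the same placement in the same bout share the motion
    realization (keyed by participant, configuration, placement, speed) and
    differ only by device noise, so between-device reliability has the
    shared-signal structure of the real experiment.  Per-participant gait
    amplitude varies lognormally (sd ``subject_scale_sd``), providing the
    between-subject variance the ICC measures.
    """
    manifest = study_manifest(design)
    participants = simulate_participants(design)
    scale_rng = _rng(design.seed, 202)
    subject_scale = {f"p{p}": float(np.exp(scale_rng.normal(0, design.subject_scale_sd)))
                     for p in range(1, design.n_participants + 1)}

    signals = []
    for rec in manifest:
        p_num = int(rec.participant_id[1:])
        i = design.speeds.index(rec.speed_kmh)
        model = GaitModel.for_speed(rec.speed_kmh, placement=rec.placement,
                                    subject_scale=subject_scale[rec.participant_id],
                                    noise_sd_g=design.motion_noise_sd_g)
        # shared-motion key: same placement in the same bout → same realization
        place_key = 1 if rec.placement == "wrist" else 2
        motion_seed_key = (design.seed, p_num, rec.configuration, place_key, i)
        n = int(round(design.bout_minutes * 60 * design.fs_hz))
        t = np.arange(n) / design.fs_hz
        mrng = _rng(*motion_seed_key)
        phases = mrng.uniform(0, 2 * np.pi, size=model.harmonics)
        motion = _harmonic_motion(model, t, phases)
        motion_noise = {ax: mrng.normal(0, model.noise_sd_g, n) for ax in ("x", "y", "z")}
        # device-noise key additionally includes the sensor index
        drng = _rng(design.seed, p_num, rec.configuration, place_key, i, sensor_key(rec, design))
        dn_sd = design.device_noise_sd_g.get(rec.device, 0.0)
        device_noise = {ax: (drng.normal(0, dn_sd, n) if dn_sd > 0 else np.zeros(n))
                        for ax in ("x", "y", "z")}
        signals.append(_assemble(model, t, motion, motion_noise, device_noise,
                                 record_id=rec.record_id, device=rec.device,
                                 fs_hz=design.fs_hz,
                                 dynamic_range_g=DEVICE_RANGE_G.get(rec.device, 8.0)))
    return manifest, signals, participants


def sensor_key(rec: ManifestRecord, design: SimDesign) -> int:
    """Recover the sensor index of a manifest record from the design layout."""
    for sensor in design.sensors:
        if (sensor.device == rec.device
                and sensor.placement_by_config[rec.configuration] == rec.placement):
            # two sensors can share device+placement only in pathological designs
            candidates = [s for s in design.sensors
                          if s.device == rec.device
                          and s.placement_by_config[rec.configuration] == rec.placement]
            if len(candidates) == 1:
                return sensor.index
            # disambiguate via the record ID scheme
            body = rec.record_id.removeprefix("t")
            return 1 if len(body) == 3 else int(body[2])
    raise DataError(f"{rec.record_id}: no sensor in design matches this record")
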