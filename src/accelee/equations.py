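"""MET prediction equations, individual RMR correction, intensity classes.

Five published count-based MET equations are evaluated per record (Freedson
1998 and Crouter 2010 on the vertical axis; Santos-Lozano 2013 VT/VM and
Sasaki 2011), each also in a *corrected* form that rescales the conventional
3.5 mL O₂·kg⁻¹·min⁻¹ MET to the individual's resting metabolic rate
predicted by the Harris–Benedict equations.  Gender is coded 1 = female,
2 = male and enters the Santos-Lozano equations as that raw integer code.

All equation functions accept ``validate=False`` to permit degenerate
arguments (zero body mass, zero height) when checking intercepts; normal use
leaves validation on.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass
from pathlib import Path
from typing import Iterable

import math

import pandas as pd

from .counts import EpochSummary
from .errors import DataError, DomainError

FEMALE, MALE = 1, 2

#: MET value of one conventional resting unit, mL O₂·kg⁻¹·min⁻¹.
STANDARD_RMR_MLKGMIN = 3.5

#: IDs of the five published equations, in table order.
EQUATION_IDS = ("freedson1998", "crouter2010", "santoslozano_vt",
                "santoslozano_vm", "sasaki2011")
#: The ten per-record outputs: each equation plain, then corrected.
ALL_EQUATION_IDS = EQUATION_IDS + tuple(f"{e}_corrected" for e in EQUATION_IDS)

INTENSITY_LEVELS = ("light", "moderate", "vigorous", "very_vigorous")


@dataclass
class Participant:
    """Anthropometrics feeding the equations and the RMR correction.

    ``height_m`` is stored in metres; the Harris–Benedict evaluation converts
    to centimetres internally.  Pass ``validate=False`` only for degenerate
    intercept checks.
    """

    participant_id: str
    age: float            # years
    body_mass_kg: float
    height_m: float
    gender_code: int      # 1 = female, 2 = male
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        if self.age <= 0:
            raise DataError(f"{self.participant_id}: age must be > 0")
        if self.body_mass_kg <= 0:
            raise DataError(f"{self.participant_id}: body mass must be > 0")
        if self.height_m <= 0:
            raise DataError(f"{self.participant_id}: height must be > 0")
        if self.gender_code not in (FEMALE, MALE):
            raise DomainError(
                f"{self.participant_id}: gender_code must be 1 (female) or 2 (male)"
            )


@dataclass
class EEResult:
    """Ten MET values (five equations × plain/corrected) plus intensity classes."""

    record_id: str
    mets: dict[str, float]
    intensity: dict[str, str]


def freedson1998(ac_vt_cpm: float, *, validate: bool = True) -> float:
    """Freedson et al. 1998 vertical-axis walking/running equation (METs)."""
    if validate and ac_vt_cpm < 0:
        raise DomainError("ac_vt_cpm must be >= 0")
    return 1.439008 + 7.95e-4 * ac_vt_cpm


def crouter2010(ac_vt_c10s: float, *, validate: bool = True) -> float:
    """Crouter et al. 2010 walking/running branch (METs).

    Exponential in the 10-s vertical-axis counts:
    ``2.294275 · exp(8.4679e−5 · AC_VT′)``.
    """
    if validate and ac_vt_c10s < 0:
        raise DomainError("ac_vt_c10s must be >= 0")
    return 2.294275 * math.exp(8.4679e-5 * ac_vt_c10s)


def santoslozano_vt(ac_vt_cpm: float, body_mass_kg: float, gender_code: int,
                    *, validate: bool = True) -> float:
    """Santos-Lozano et al. 2013 vertical-axis equation for adults (METs)."""
    if validate:
        if ac_vt_cpm < 0:
            raise DomainError("ac_vt_cpm must be >= 0")
        if body_mass_kg <= 0:
            raise DomainError("body_mass_kg must be > 0")
        if gender_code not in (FEMALE, MALE):
            raise DomainError("gender_code must be 1 (female) or 2 (male)")
    return 3.4002 + 5.3e-4 * ac_vt_cpm - 5.564e-2 * body_mass_kg + 1.2789 * gender_code


def santoslozano_vm(ac_vm_cpm: float, body_mass_kg: float, gender_code: int,
                    *, validate: bool = True) -> float:
    """Santos-Lozano et al. 2013 vector-magnitude equation for adults (METs)."""
    if validate:
        if ac_vm_cpm < 0:
            raise DomainError("ac_vm_cpm must be >= 0")
        if body_mass_kg <= 0:
            raise DomainError("body_mass_kg must be > 0")
        if gender_code not in (FEMALE, MALE):
            raise DomainError("gender_code must be 1 (female) or 2 (male)")
    return 2.8323 + 5.4e-4 * ac_vm_cpm - 5.912e-2 * body_mass_kg + 1.4410 * gender_code


def sasaki2011(ac_vm_cpm: float, *, validate: bool = True) -> float:
    """Sasaki et al. 2011 vector-magnitude equation (METs)."""
    if validate and ac_vm_cpm < 0:
        raise DomainError("ac_vm_cpm must be >= 0")
    return 8.63e-4 * ac_vm_cpm + 0.668876


def harris_benedict(p: Participant) -> float:
    """Harris–Benedict basal energy expenditure, kcal/day (gender-dispatched)."""
    height_cm = p.height_m * 100.0
    if p.gender_code == FEMALE:
        return 655.0955 + 1.8496 * height_cm + 9.5634 * p.body_mass_kg - 4.6756 * p.age
    if p.gender_code == MALE:
        return 66.4730 + 5.0033 * height_cm + 13.7516 * p.body_mass_kg - 6.7550 * p.age
    raise DomainError(f"{p.participant_id}: gender_code must be 1 or 2")


def resting_vo2_mlkgmin(p: Participant) -> float:
    """Individual resting metabolic rate in mL O₂·kg⁻¹·min⁻¹.

    Converts Harris–Benedict kcal/day to oxygen uptake per kg per minute:
    ÷1440 min/day, ÷5 kcal per litre O₂, ×1000 mL/L, ÷ body mass.
    """
    hb = harris_benedict(p)
    if hb <= 0:
        raise DataError(f"{p.participant_id}: Harris–Benedict RMR non-positive ({hb:.3f})")
    return hb * 1000.0 / (1440.0 * 5.0 * p.body_mass_kg)


def corrected_mets(mets: float, p: Participant, *, validate: bool = True) -> float:
    """Rescale a 3.5-based MET value to the individual's predicted RMR.

    ``corrected = mets × 3.5 / RMR`` with RMR from :func:`resting_vo2_mlkgmin`;
    a person whose predicted RMR is exactly 3.5 mL·kg⁻¹·min⁻¹ is unchanged.
    """
    if validate and mets < 0:
        raise DomainError("mets must be >= 0")
    return mets * STANDARD_RMR_MLKGMIN / resting_vo2_mlkgmin(p)


def classify_intensity(mets: float) -> str:
    """Intensity category from METs: [0,1.5) light, [1.5,3) moderate, [3,6)
    vigorous, ≥6 very vigorous."""
    if mets < 0:
        raise DomainError("mets must be >= 0")
    if mets < 1.5:
        return "light"
    if mets < 3.0:
        return "moderate"
    if mets < 6.0:
        return "vigorous"
    return "very_vigorous"


def compute_all(epoch: EpochSummary, p: Participant) -> EEResult:
    """All ten MET values and intensity classes for one record."""
    plain = {
        "freedson1998": lambda: freedson1998(epoch.ac_vt_cpm),
        "crouter2010": lambda: crouter2010(epoch.ac_vt_c10s),
        "santoslozano_vt": lambda: santoslozano_vt(epoch.ac_vt_cpm, p.body_mass_kg, p.gender_code),
        "santoslozano_vm": lambda: santoslozano_vm(epoch.ac_vm_cpm, p.body_mass_kg, p.gender_code),
        "sasaki2011": lambda: sasaki2011(epoch.ac_vm_cpm),
    }
    mets: dict[str, float] = {}
    for eq_id, fn in plain.items():
        try:
            mets[eq_id] = fn()
        except Exception as exc:  # annotate with the failing equation
            raise type(exc)(f"{epoch.record_id}/{eq_id}: {exc}") from exc
    for eq_id in EQUATION_IDS:
        try:
            # validate=False: a linear equation can go (slightly) negative at
            # low counts; the multiplicative correction is applied as-is and
            # only the intensity classification clamps at zero.
            mets[f"{eq_id}_corrected"] = corrected_mets(mets[eq_id], p, validate=False)
        except Exception as exc:
            raise type(exc)(f"{epoch.record_id}/{eq_id}_corrected: {exc}") from exc
    intensity = {eq_id: classify_intensity(max(v, 0.0)) for eq_id, v in mets.items()}
    return EEResult(record_id=epoch.record_id, mets=mets, intensity=intensity)


# ---------------------------------------------------------------------------
# Participant / result file I/O
# ---------------------------------------------------------------------------

def read_participants(path: str | Path, height_unit: str = "m") -> list[Participant]:
    """Participants CSV: id, age, body_mass_kg, height_m (or height_cm), gender_code.

    ``height_unit='cm'`` divides the height column by 100 on read.
    """
    df = pd.read_csv(path)
    height_col = "height_m" if "height_m" in df.columns else "height_cm"
    if height_col not in df.columns:
        raise DataError(f"{Path(path).name}: missing height column")
    scale = 1.0 if height_unit == "m" and height_col == "height_m" else None
    if scale is None:
        scale = 0.01 if (height_unit == "cm" or height_col == "height_cm") else 1.0
    return [
        Participant(
            participant_id=str(row["id"]),
            age=float(row["age"]),
            body_mass_kg=float(row["body_mass_kg"]),
            height_m=float(row[height_col]) * scale,
            gender_code=int(row["gender_code"]),
        )
        for _, row in df.iterrows()
    ]


def write_participants(participants: Iterable[Participant], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([
        {"id": p.participant_id, "age": p.age, "body_mass_kg": p.body_mass_kg,
         "height_m": p.height_m, "gender_code": p.gender_code}
        for p in participants
    ])
    df.to_csv(path, index=False, float_format="%.4f", lineterminator="\r\n")
    return path


def write_ee_csv(results: Iterable[EEResult], path: str | Path) -> Path:
    """Long-format EE results: one row per record × equation."""
    path = Path(path)
    rows = []
    for r in results:
        for eq_id in ALL_EQUATION_IDS:
            base = eq_id.removesuffix("_corrected")
            rows.append({
                "record_id": r.record_id,
                "equation_id": base,
                "corrected": eq_id.endswith("_corrected"),
                "mets": r.mets[eq_id],
                "intensity": r.intensity[eq_id],
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f", lineterminator="\r\n")
    return path
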