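"""Composite early-brain-injury (EBI) grading after aneurysmal SAH.

The grade (1-5) combines three admission findings:

* one point for persistent loss of consciousness,
* one point for global cerebral edema,
* 1-3 points for the total intracranial blood burden.

The blood burden sums the Hijdra cisternal score (subarachnoid blood in ten
cisterns/fissures, 0-3 each, 0-30 total), the Le Roux score (intraventricular
blood in four ventricles, 0-4 each, 0-16 total) and 0-3 points for the
intraparenchymal hematoma volume estimated by the ABC/2 ellipsoid formula
(< 10 mL -> 1, 10-30 mL -> 2, > 30 mL -> 3; no hematoma -> 0). The maximum
burden is therefore 30 + 16 + 3 = 49, categorized low (0-19), moderate
(20-29) or high (30-49) for 1, 2 or 3 category points. A grade >= 3 is
classified as severe EBI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "BloodBurdenInputs",
    "EbiAssessment",
    "hijdra_cisternal",
    "leroux",
    "abc2_volume",
    "ich_points",
    "blood_burden",
    "burden_category_points",
    "ebi_grade",
    "classify_ebi",
    "assess_ebi",
]

N_CISTERNS = 10
N_VENTRICLES = 4
BURDEN_MAX = 49
SEVERE_THRESHOLD = 3


class EbiValidationError(ValueError):
    """Raised for imaging/clinical inputs outside their declared ranges."""


@dataclass(frozen=True)
class BloodBurdenInputs:
    """Imaging inputs for the blood-burden score.

    ``hematoma_diameters`` holds the three orthogonal diameters (A, B, C) in
    cm of an intraparenchymal hematoma, or ``None`` when no hematoma is seen.
    """

    cistern_grades: Sequence[int]
    ventricle_grades: Sequence[int]
    hematoma_diameters: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        hijdra_cisternal(self.cistern_grades)  # range/count validation
        leroux(self.ventricle_grades)
        if self.hematoma_diameters is not None:
            abc2_volume(*self.hematoma_diameters)


@dataclass(frozen=True)
class EbiAssessment:
    hijdra: int
    leroux: int
    ich_volume_ml: float
    ich_points: int
    burden_total: int
    burden_points: int
    loc: bool
    edema: bool
    grade: int
    severe: bool


def hijdra_cisternal(cistern_grades: Sequence[int]) -> int:
    """Sum the ten cisternal blood grades (0-3 each); range 0-30."""
    if len(cistern_grades) != N_CISTERNS:
        raise EbiValidationError(
            f"expected {N_CISTERNS} cisternal grades, got {len(cistern_grades)}"
        )
    for i, g in enumerate(cistern_grades):
        if g not in (0, 1, 2, 3):
            raise EbiValidationError(
                f"cistern grade at index {i} must be in 0..3, got {g}"
            )
    return int(sum(cistern_grades))


def leroux(ventricle_grades: Sequence[int]) -> int:
    """Sum the four per-ventricle blood grades (0-4 each, 0 = no blood);
    range 0-16."""
    if len(ventricle_grades) != N_VENTRICLES:
        raise EbiValidationError(
            f"expected {N_VENTRICLES} ventricle grades, got {len(ventricle_grades)}"
        )
    for i, g in enumerate(ventricle_grades):
        if g not in (0, 1, 2, 3, 4):
            raise EbiValidationError(
                f"ventricle grade at index {i} must be in 0..4, got {g}"
            )
    return int(sum(ventricle_grades))


def abc2_volume(a_cm: float, b_cm: float, c_cm: float) -> float:
    """Ellipsoid hematoma volume A*B*C/2 in mL from orthogonal diameters in cm."""
    for name, v in (("A", a_cm), ("B", b_cm), ("C", c_cm)):
        if not v > 0:
            raise EbiValidationError(f"diameter {name} must be positive, got {v}")
    return a_cm * b_cm * c_cm / 2.0


def ich_points(volume_ml: float, has_hematoma: bool = True) -> int:
    """Points for intraparenchymal hematoma volume.

    No hematoma scores 0; otherwise 1 for < 10 mL, 2 for 10-30 mL (both ends
    inclusive), 3 for > 30 mL.
    """
    if volume_ml < 0:
        raise EbiValidationError(f"volume must be non-negative, got {volume_ml}")
    if not has_hematoma or volume_ml == 0:
        return 0
    if volume_ml < 10:
        return 1
    if volume_ml <= 30:
        return 2
    return 3


def blood_burden(hijdra: int, leroux: int, ich_points: int) -> int:
    """Total intracranial blood burden: Hijdra + Le Roux + ICH points (0-49)."""
    if not 0 <= hijdra <= 30:
        raise EbiValidationError(f"hijdra must be in 0..30, got {hijdra}")
    if not 0 <= leroux <= 16:
        raise EbiValidationError(f"leroux must be in 0..16, got {leroux}")
    if not 0 <= ich_points <= 3:
        raise EbiValidationError(f"ich_points must be in 0..3, got {ich_points}")
    return hijdra + leroux + ich_points


def burden_category_points(burden_total: int) -> int:
    """Category points: low 0-19 -> 1, moderate 20-29 -> 2, high 30-49 -> 3."""
    if not 0 <= burden_total <= BURDEN_MAX:
        raise EbiValidationError(
            f"burden_total must be in 0..{BURDEN_MAX}, got {burden_total}"
        )
    if burden_total <= 19:
        return 1
    if burden_total <= 29:
        return 2
    return 3


def ebi_grade(loc: bool, edema: bool, burden_points: int) -> int:
    """EBI grade = loss-of-consciousness point + edema point + burden
    category points; range 1-5."""
    if burden_points not in (1, 2, 3):
        raise EbiValidationError(
            f"burden_points must be in {{1, 2, 3}}, got {burden_points}"
        )
    return int(bool(loc)) + int(bool(edema)) + burden_points


def classify_ebi(grade: int) -> str:
    """Classify a grade as ``"severe"`` (>= 3) or ``"mild"``."""
    if not 1 <= grade <= 5:
        raise EbiValidationError(f"grade must be in 1..5, got {grade}")
    return "severe" if grade >= SEVERE_THRESHOLD else "mild"


def assess_ebi(inputs: BloodBurdenInputs, loc: bool, edema: bool) -> EbiAssessment:
    """Full EBI assessment from imaging and consciousness findings."""
    h = hijdra_cisternal(inputs.cistern_grades)
    lr = leroux(inputs.ventricle_grades)
    if inputs.hematoma_diameters is None:
        volume, ich = 0.0, 0
    else:
        volume = abc2_volume(*inputs.hematoma_diameters)
        ich = ich_points(volume)
    burden = blood_burden(h, lr, ich)
    bp = burden_category_points(burden)
    grade = ebi_grade(loc, edema, bp)
    return EbiAssessment(
        hijdra=h,
        leroux=lr,
        ich_volume_ml=volume,
        ich_points=ich,
        burden_total=burden,
        burden_points=bp,
        loc=bool(loc),
        edema=bool(edema),
        grade=grade,
        severe=grade >= SEVERE_THRESHOLD,
    )
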