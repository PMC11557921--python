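"""Logistic Organ Dysfunction System (LODS) scoring.

LODS grades the worst values observed during the first 24 ICU hours across
six organ systems — neurologic (GCS), cardiovascular (heart rate, systolic
blood pressure), renal (serum urea, creatinine, 24-h urine output),
pulmonary (PaO2/FiO2 under ventilation or CPAP), hematologic (leucocytes,
platelets) and hepatic (bilirubin, prothrombin time) — and sums the six
per-system point values into a total of 0–22 points. Each system's score is
the maximum severity triggered by any of its variables. The total is also
reported with the neurologic (GCS) component removed, to isolate
extracerebral organ dysfunction (range 0–17).

Missing variables are scored as physiologically normal (0 points) and
recorded in ``LodsBreakdown.missing_fields`` so that retrospective tables
with gaps remain usable while the imputation stays auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

from pydantic import BaseModel, model_validator

__all__ = [
    "OrganObservations",
    "LodsBreakdown",
    "score_neurologic",
    "score_cardiovascular",
    "score_renal",
    "score_pulmonary",
    "score_hematologic",
    "score_hepatic",
    "compute_lods",
]

#: Per-system attainable point sets; the total 0-22 decomposes over these.
SYSTEM_POINT_SETS = {
    "neurologic": (0, 1, 3, 5),
    "cardiovascular": (0, 1, 3, 5),
    "renal": (0, 1, 3, 5),
    "pulmonary": (0, 1, 3),
    "hematologic": (0, 1, 3),
    "hepatic": (0, 1),
}

LODS_MAX = 22
LODS_MAX_WITHOUT_GCS = 17


class LodsValidationError(ValueError):
    """Raised when an observation value is outside its physiologic domain."""


class OrganObservations(BaseModel):
    """Worst first-24-hour physiology and laboratory values for one patient.

    Every field is optional: a missing value is treated as normal at scoring
    time (and flagged). ``pao2_fio2`` is interpreted in mmHg unless
    ``pao2_fio2_unit`` is set to ``"kPa"``; no silent conversion is done.
    """

    gcs_min: Optional[int] = None
    hr_min: Optional[float] = None
    hr_max: Optional[float] = None
    sbp_min: Optional[float] = None
    sbp_max: Optional[float] = None
    urea_max: Optional[float] = None  # mmol/L
    creatinine_max: Optional[float] = None  # mg/dL
    urine_24h: Optional[float] = None  # L/day
    ventilated_or_cpap: Optional[bool] = None
    pao2_fio2: Optional[float] = None
    pao2_fio2_unit: Literal["mmHg", "kPa"] = "mmHg"
    wbc_min: Optional[float] = None  # x10^9/L
    wbc_max: Optional[float] = None
    platelets_min: Optional[float] = None  # x10^9/L
    bilirubin_max: Optional[float] = None  # mg/dL
    pt_excess_sec: Optional[float] = None  # seconds above control

    @model_validator(mode="after")
    def _check_domains(self) -> "OrganObservations":
        if self.gcs_min is not None and not 3 <= self.gcs_min <= 15:
            raise LodsValidationError(
                f"gcs_min must be in [3, 15], got {self.gcs_min}"
            )
        for name in (
            "hr_min", "hr_max", "sbp_min", "sbp_max", "urea_max",
            "creatinine_max", "urine_24h", "pao2_fio2", "wbc_min",
            "wbc_max", "platelets_min", "bilirubin_max",
        ):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise LodsValidationError(
                    f"{name} must be a finite non-negative number, got {v}"
                )
        for lo, hi in (("hr_min", "hr_max"), ("sbp_min", "sbp_max"),
                       ("wbc_min", "wbc_max")):
            a, b = getattr(self, lo), getattr(self, hi)
            if a is not None and b is not None and a > b:
                raise LodsValidationError(f"{lo} ({a}) exceeds {hi} ({b})")
        return self

    def observed_fields(self) -> list[str]:
        return [
            name for name in type(self).model_fields
            if name != "pao2_fio2_unit" and getattr(self, name) is not None
        ]


@dataclass(frozen=True)
class LodsBreakdown:
    """Per-system LODS points plus totals with and without the GCS term."""

    neurologic: int
    cardiovascular: int
    renal: int
    pulmonary: int
    hematologic: int
    hepatic: int
    total: int
    total_without_gcs: int
    missing_fields: list[str] = field(default_factory=list)

    def system_points(self) -> dict[str, int]:
        return {s: getattr(self, s) for s in SYSTEM_POINT_SETS}


def score_neurologic(gcs_min: int) -> int:
    """Neurologic points from the minimum GCS: 3-5 -> 5, 6-8 -> 3, 9-13 -> 1,
    14-15 -> 0."""
    if not 3 <= gcs_min <= 15:
        raise LodsValidationError(f"gcs_min must be in [3, 15], got {gcs_min}")
    if gcs_min <= 5:
        return 5
    if gcs_min <= 8:
        return 3
    if gcs_min <= 13:
        return 1
    return 0


def score_cardiovascular(hr_min: float, hr_max: float,
                         sbp_min: float, sbp_max: float) -> int:
    """Cardiovascular points from heart-rate and systolic-pressure extremes.

    Severe bradycardia (HR < 30) or profound hypotension (SBP < 40) scores 5;
    SBP 40-69 or >= 270 scores 3; SBP 70-89, SBP 240-269 or tachycardia
    (HR >= 140) scores 1.
    """
    for name, v in (("hr_min", hr_min), ("hr_max", hr_max),
                    ("sbp_min", sbp_min), ("sbp_max", sbp_max)):
        if v < 0:
            raise LodsValidationError(f"{name} must be non-negative, got {v}")
    if hr_min > hr_max or sbp_min > sbp_max:
        raise LodsValidationError("extremes must satisfy min <= max")
    if hr_min < 30 or sbp_min < 40:
        return 5
    if 40 <= sbp_min < 70 or sbp_max >= 270:
        return 3
    if 70 <= sbp_min < 90 or hr_max >= 140 or 240 <= sbp_max < 270:
        return 1
    return 0


def score_renal(urea_max: float, creatinine_max: float, urine_24h: float) -> int:
    """Renal points: worst of urea (mmol/L), creatinine (mg/dL) and 24-h urine
    output (L). Both oliguria (< 0.5 L) and polyuria (>= 10 L) score."""
    for name, v in (("urea_max", urea_max), ("creatinine_max", creatinine_max),
                    ("urine_24h", urine_24h)):
        if v < 0:
            raise LodsValidationError(f"{name} must be non-negative, got {v}")
    if urea_max >= 20:
        urea_pts = 5
    elif urea_max >= 10:
        urea_pts = 3
    elif urea_max >= 6:
        urea_pts = 1
    else:
        urea_pts = 0
    if creatinine_max >= 1.60:
        creat_pts = 3
    elif creatinine_max >= 1.20:
        creat_pts = 1
    else:
        creat_pts = 0
    if urine_24h < 0.5:
        urine_pts = 5
    elif urine_24h < 0.75:
        urine_pts = 3
    elif urine_24h < 10:
        urine_pts = 0
    else:
        urine_pts = 3
    return max(urea_pts, creat_pts, urine_pts)


def score_pulmonary(ventilated_or_cpap: bool, pao2_fio2: Optional[float],
                    unit: Literal["mmHg", "kPa"] = "mmHg") -> int:
    """Pulmonary points: 0 when breathing spontaneously without CPAP; on
    ventilation or CPAP, 1 for PaO2/FiO2 >= 150 mmHg (19.9 kPa), 3 below."""
    if not ventilated_or_cpap:
        return 0
    if pao2_fio2 is None:
        raise LodsValidationError(
            "pao2_fio2 is required when ventilated_or_cpap is set"
        )
    if pao2_fio2 < 0:
        raise LodsValidationError(f"pao2_fio2 must be non-negative, got {pao2_fio2}")
    threshold = 19.9 if unit == "kPa" else 150.0
    return 1 if pao2_fio2 >= threshold else 3


def score_hematologic(wbc_min: float, wbc_max: float, platelets_min: float) -> int:
    """Hematologic points from leucocyte extremes and the platelet nadir.

    Severe leucopenia (< 1.0) scores 3; leucopenia 1.0-2.4, extreme
    leucocytosis (>= 50) or thrombocytopenia (< 50) score 1.
    """
    for name, v in (("wbc_min", wbc_min), ("wbc_max", wbc_max),
                    ("platelets_min", platelets_min)):
        if v < 0:
            raise LodsValidationError(f"{name} must be non-negative, got {v}")
    if wbc_min > wbc_max:
        raise LodsValidationError("wbc_min exceeds wbc_max")
    if wbc_min < 1.0:
        wbc_pts = 3
    elif wbc_min < 2.5 or wbc_max >= 50:
        wbc_pts = 1
    else:
        wbc_pts = 0
    plt_pts = 1 if platelets_min < 50 else 0
    return max(wbc_pts, plt_pts)


def score_hepatic(bilirubin_max: float, pt_excess_sec: float) -> int:
    """Hepatic points: 1 for bilirubin >= 2.0 mg/dL or prothrombin time more
    than 3 s above control, else 0."""
    if bilirubin_max < 0:
        raise LodsValidationError(
            f"bilirubin_max must be non-negative, got {bilirubin_max}"
        )
    return 1 if bilirubin_max >= 2.0 or pt_excess_sec > 3 else 0


# Normal fallbacks applied when a variable is missing (scored as 0 points).
_NORMALS: dict[str, object] = {
    "gcs_min": 15,
    "hr_min": 80.0, "hr_max": 80.0,
    "sbp_min": 120.0, "sbp_max": 120.0,
    "urea_max": 4.0, "creatinine_max": 0.9, "urine_24h": 1.5,
    "ventilated_or_cpap": False, "pao2_fio2": None,
    "wbc_min": 8.0, "wbc_max": 8.0, "platelets_min": 250.0,
    "bilirubin_max": 0.8, "pt_excess_sec": 0.0,
}


def compute_lods(obs: OrganObservations, include_gcs: bool = True) -> LodsBreakdown:
    """Score all six organ systems and sum across systems.

    Missing variables contribute 0 points and are listed in
    ``missing_fields``. When ``include_gcs`` is false the computed points are
    identical but ``total_without_gcs`` is the headline score for callers.

    Raises
    ------
    LodsValidationError
        If every field is missing (nothing to score) or a value is invalid.
    """
    observed = obs.observed_fields()
    if not observed:
        raise LodsValidationError("all observation fields are missing; nothing to score")
    missing = sorted(
        name for name in _NORMALS
        if name != "pao2_fio2" and getattr(obs, name) is None
    )

    def get(name: str):
        v = getattr(obs, name)
        return _NORMALS[name] if v is None else v

    neuro = score_neurologic(get("gcs_min"))
    cardio = score_cardiovascular(get("hr_min"), get("hr_max"),
                                  get("sbp_min"), get("sbp_max"))
    renal = score_renal(get("urea_max"), get("creatinine_max"), get("urine_24h"))
    pulm = score_pulmonary(get("ventilated_or_cpap"), obs.pao2_fio2,
                           obs.pao2_fio2_unit)
    hema = score_hematologic(get("wbc_min"), get("wbc_max"), get("platelets_min"))
    hepa = score_hepatic(get("bilirubin_max"), get("pt_excess_sec"))
    total = neuro + cardio + renal + pulm + hema + hepa
    return LodsBreakdown(
        neurologic=neuro,
        cardiovascular=cardio,
        renal=renal,
        pulmonary=pulm,
        hematologic=hema,
        hepatic=hepa,
        total=total,
        total_without_gcs=total - neuro,
        missing_fields=missing,
    )
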