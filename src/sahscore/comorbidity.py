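"""Charlson Comorbidity Index (CCI), classical non-age-adjusted weights.

Age enters the downstream multivariate outcome model as its own covariate,
so the original weight table is used without the age adjustment: one point
for each condition in the first block, two for hemiplegia, moderate/severe
renal disease, diabetes with end-organ damage, any tumor, leukemia or
lymphoma, three for moderate/severe liver disease, and six for metastatic
solid tumor or AIDS.
"""

from __future__ import annotations

from pydantic import BaseModel, model_validator

__all__ = ["ComorbidityFlags", "charlson_index", "CHARLSON_WEIGHTS"]


class ComorbidityError(ValueError):
    """Raised for mutually exclusive severity flags set together."""


CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "connective_tissue_disease": 1,
    "ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes": 1,
    "hemiplegia": 2,
    "moderate_severe_renal_disease": 2,
    "diabetes_end_organ_damage": 2,
    "any_tumor": 2,
    "leukemia": 2,
    "lymphoma": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids": 6,
}

# (mild, severe) pairs that must not both be flagged; the severe form
# supersedes the mild one in coding.
_EXCLUSIVE_PAIRS = (
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("diabetes", "diabetes_end_organ_damage"),
    ("any_tumor", "metastatic_solid_tumor"),
)


class ComorbidityFlags(BaseModel):
    myocardial_infarction: bool = False
    congestive_heart_failure: bool = False
    peripheral_vascular_disease: bool = False
    cerebrovascular_disease: bool = False
    dementia: bool = False
    chronic_pulmonary_disease: bool = False
    connective_tissue_disease: bool = False
    ulcer_disease: bool = False
    mild_liver_disease: bool = False
    diabetes: bool = False
    hemiplegia: bool = False
    moderate_severe_renal_disease: bool = False
    diabetes_end_organ_damage: bool = False
    any_tumor: bool = False
    leukemia: bool = False
    lymphoma: bool = False
    moderate_severe_liver_disease: bool = False
    metastatic_solid_tumor: bool = False
    aids: bool = False

    @model_validator(mode="after")
    def _no_conflicting_severity(self) -> "ComorbidityFlags":
        for mild, severe in _EXCLUSIVE_PAIRS:
            if getattr(self, mild) and getattr(self, severe):
                raise ComorbidityError(
                    f"conflicting severity flags: {mild} and {severe} "
                    "cannot both be true"
                )
        return self


def charlson_index(flags: ComorbidityFlags) -> int:
    """Weighted sum of comorbid conditions; 0 for a patient with none."""
    return sum(w for name, w in CHARLSON_WEIGHTS.items() if getattr(flags, name))
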