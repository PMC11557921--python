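"""Published summary tables of the reference aSAH cohort (n = 324).

These are the frequency columns of the retrospective single-center cohort
the pipeline was designed around: EBI grade, LODS score and 3-month mRS
distributions, plus the cohort anchors (age, treatment split, prevalences).
Only summary-level counts were published, so they serve two roles here:

* calibration marginals for the synthetic-cohort generator, and
* worked-example inputs for the distribution-summary operations
  (prevalence of severe EBI, median grade, in-hospital mortality).

Note the published mRS column is internally inconsistent (it sums to 323
and its mRS 0-2 share disagrees slightly with the stated 73% favorable
rate); the counts are kept exactly as printed and the inconsistency is
documented in the methods note.
"""

from __future__ import annotations

import numpy as np

N_PATIENTS = 324

#: EBI grade -> patient count.
EBI_GRADE_COUNTS: dict[int, int] = {1: 118, 2: 82, 3: 66, 4: 45, 5: 13}

#: LODS total -> patient count (scores absent from the table have count 0).
LODS_SCORE_COUNTS: dict[int, int] = {
    1: 3, 2: 10, 3: 26, 4: 30, 5: 49, 6: 55, 7: 48, 8: 17,
    9: 24, 10: 8, 11: 39, 12: 3, 13: 5, 14: 4, 15: 0, 16: 3,
}

#: mRS at 3 months -> patient count, as printed (sums to 323).
MRS_COUNTS: dict[int, int] = {0: 113, 1: 87, 2: 25, 3: 22, 4: 32, 5: 22, 6: 22}

AGE_MEAN = 55.9
AGE_SD = 13.6
CLIPPING_FRACTION = 173 / 324
SEVERE_EBI_PREVALENCE = 124 / 324
UNFAVORABLE_PREVALENCE = 0.27  # stated 73% favorable
IN_HOSPITAL_MORTALITY = 22 / 324


def expand_counts(counts: dict[int, int]) -> np.ndarray:
    """Expand a value -> count table into the per-patient value vector."""
    return np.repeat(
        np.fromiter(counts.keys(), dtype=int),
        np.fromiter(counts.values(), dtype=int),
    )


def lods_marginal(max_score: int = 22) -> np.ndarray:
    """Default LODS-total probability vector over 0..max_score, from the
    reference frequency column renormalized."""
    p = np.zeros(max_score + 1)
    for k, c in LODS_SCORE_COUNTS.items():
        p[k] = c
    return p / p.sum()


def ebi_grade_marginal() -> np.ndarray:
    """Reference EBI-grade probability vector over grades 1..5."""
    c = np.array([EBI_GRADE_COUNTS[g] for g in range(1, 6)], dtype=float)
    return c / c.sum()
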