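"""Recompute the reference cohort's published summary statistics.

Only summary-level frequency tables of the original cohort (n = 324) are
available; this driver expands them to per-patient vectors and runs the
package's own summary operations on them: severe-EBI prevalence, median
EBI grade with its distribution-free CI, median LODS, and in-hospital
mortality. Writes results/reference_summaries.json.
"""

import json
from pathlib import Path

from sahscore import classify_ebi, median_with_ci
from sahscore import reference_cohort as ref

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

grades = ref.expand_counts(ref.EBI_GRADE_COUNTS)
lods = ref.expand_counts(ref.LODS_SCORE_COUNTS)
mrs = ref.expand_counts(ref.MRS_COUNTS)

severe = sum(classify_ebi(int(g)) == "severe" for g in grades)
ebi_med, ebi_lo, ebi_hi = median_with_ci(grades)
lods_med, lods_lo, lods_hi = median_with_ci(lods)
deaths = int((mrs == 6).sum())

summary = {
    "n_patients": ref.N_PATIENTS,
    "severe_ebi_percent": 100 * severe / ref.N_PATIENTS,
    "severe_ebi_count": severe,
    "median_ebi_grade": ebi_med,
    "median_ebi_grade_ci": [ebi_lo, ebi_hi],
    "median_lods": lods_med,
    "median_lods_ci": [lods_lo, lods_hi],
    "in_hospital_mortality_percent": 100 * deaths / ref.N_PATIENTS,
    "in_hospital_deaths": deaths,
}
out = RESULTS / "reference_summaries.json"
out.write_text(json.dumps(summary, indent=2) + "\n")

print(f"reference cohort (n={ref.N_PATIENTS}):")
print(f"  severe EBI: {summary['severe_ebi_percent']:.1f}% ({severe}/{ref.N_PATIENTS})")
print(f"  median EBI grade: {ebi_med:g} (95%CI {ebi_lo:g}-{ebi_hi:g})")
print(f"  median LODS: {lods_med:g} (95%CI {lods_lo:g}-{lods_hi:g})")
print(f"  in-hospital mortality: "
      f"{summary['in_hospital_mortality_percent']:.1f}% ({deaths}/{ref.N_PATIENTS})")
print(f"-> {out}")
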