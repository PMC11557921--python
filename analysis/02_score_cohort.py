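"""Apply the three scoring stages to the study-sized cohort.

Reads results/cohort_n324.csv, appends LODS, EBI and CCI columns, writes
results/scores_n324.csv, and prints the score distributions in the shape
clinicians report them (grade/score -> % (n)).
"""

from pathlib import Path

from sahscore.io import (
    read_patient_table,
    score_cci_table,
    score_ebi_table,
    score_lods_table,
    write_table,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

cohort = read_patient_table(RESULTS / "cohort_n324.csv")
scored = score_cci_table(score_ebi_table(score_lods_table(cohort)))
out = RESULTS / "scores_n324.csv"
write_table(scored, out)
print(f"scored {len(scored)} patients -> {out}\n")

n = len(scored)
for col, label in (("ebi_grade", "EBI grade"), ("lods_total", "LODS score"),
                   ("mrs", "mRS at 3 months")):
    print(f"{label} distribution:")
    for value, count in scored[col].value_counts().sort_index().items():
        print(f"  {value:>2}: {100 * count / n:5.1f}% ({count}/{n})")
print(f"\nsevere EBI (grade >= 3): "
      f"{100 * scored['severe_ebi'].mean():.1f}% "
      f"({int(scored['severe_ebi'].sum())}/{n})")
print(f"in-hospital mortality:   "
      f"{100 * scored['died_in_hospital'].mean():.1f}% "
      f"({int(scored['died_in_hospital'].sum())}/{n})")
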