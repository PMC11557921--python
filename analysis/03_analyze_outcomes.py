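"""Discrimination and outcome analysis over the scored cohorts.

Runs the analysis stage (ROC/AUC at the fixed cutoff of 7, 2x2 diagnostic
metrics, odds ratios, simple logistic fits, and the multivariate linear
model of mRS) on the study-sized cohort, writes the typed JSON report, and
prints the headline numbers. The n = 5,000 cohort is analyzed as well to
show the AUC converging to the generator's configured discrimination target.
"""

import json
from pathlib import Path

import pandas as pd

from sahscore.io import read_patient_table
from sahscore.pipeline import run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"

for name in ("cohort_n324", "cohort_n5000"):
    cohort = read_patient_table(RESULTS / f"{name}.csv")
    scored, report = run_pipeline(cohort, cutoff=7)
    out = RESULTS / f"report_{name.split('_')[1]}.json"
    out.write_text(json.dumps(report.model_dump(), indent=2) + "\n")
    print(f"=== {name} (n={report.n_patients}) -> {out}")
    for ep in report.endpoints:
        if not ep.estimable:
            print(f"  {ep.endpoint}: not estimable ({ep.reason})")
            continue
        r = ep.roc
        m = r.metrics
        line = (f"  {ep.endpoint}: AUC {r.auc:.3f} "
                f"(95%CI {r.auc_ci_low:.3f}-{r.auc_ci_high:.3f}), cutoff {r.cutoff:g}; "
                f"sens {100 * m.sensitivity:.0f}%, spec {100 * m.specificity:.0f}%, "
                f"PPV {100 * m.ppv:.0f}%, NPV {100 * m.npv:.0f}%")
        if r.odds_ratio is not None:
            o = r.odds_ratio
            line += (f"; OR {o.odds_ratio:.2f} "
                     f"(95%CI {o.ci_low:.2f}-{o.ci_high:.2f}, p {o.p_display})")
        print(line)
    print("  multivariate linear model of mRS:")
    for row in report.multivariate.rows:
        print(f"    {row.name:>20}: estimate {row.estimate:8.4f} "
              f"(SE {row.std_error:.4f}), |t| {row.statistic:.3f}, p {row.p_display}")
    print()
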