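"""Generate the synthetic working cohorts.

Writes two seeded cohorts under results/: a study-sized cohort (n = 324,
matching the reference cohort) used by the scoring and analysis drivers,
and a larger calibration cohort (n = 5,000) on which the generator's
discrimination target can be checked with small sampling error.
"""

from pathlib import Path

from sahscore.io import write_table
from sahscore.simulate import SimConfig, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

for name, n, seed in (("cohort_n324", 324, 2024), ("cohort_n5000", 5000, 2025)):
    cfg = SimConfig(n=n, seed=seed)
    cohort = generate_cohort(cfg)
    out = RESULTS / f"{name}.csv"
    write_table(cohort, out)
    print(f"{name}: n={len(cohort)} patients, seed={seed} -> {out}")
    print(f"  severe-EBI target prevalence {cfg.prevalence_severe_ebi:.2f}, "
          f"AUC target {cfg.auc_lods_vs_severe_ebi:.2f}, "
          f"unfavorable {cfg.prevalence_unfavorable:.2f}, "
          f"mortality {cfg.mortality:.3f}")
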