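#!/usr/bin/env python
"""Accuracy-contingent pattern similarity across the simulated cohort.

For every subject, correlates the attention-task amplitude patterns (per
cued direction, split by response accuracy) with the baseline task's
correct-rejection patterns for the matching direction, and contrasts the
Fisher-transformed indices between correct and incorrect trials with a
planned paired t test.  A decoupled-fidelity control cohort shows how much
of the contrast survives when behavior is severed from the patterns.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from featattn.pipeline import SubjectConfig, cohort_summary, run_cohort
from featattn.stats import within_subject_sem

SEED = 20260104
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    warnings.filterwarnings("ignore", category=RuntimeWarning)
    OUT.mkdir(parents=True, exist_ok=True)

    results = run_cohort(12, SubjectConfig(), seed=SEED)
    summary = cohort_summary(results)
    table = pd.DataFrame({
        "subject": range(12),
        "z_correct": summary["z_correct"],
        "z_incorrect": summary["z_incorrect"],
    })
    table.to_csv(OUT / "similarity_indices.csv", index=False)
    sem = within_subject_sem(table[["z_correct", "z_incorrect"]].to_numpy())
    t = summary["similarity_contrast"]
    print("pattern similarity (Fisher z, mean +- within-subject SEM):")
    print(f"  correct   {table['z_correct'].mean():.3f} +- {sem[0]:.3f}")
    print(f"  incorrect {table['z_incorrect'].mean():.3f} +- {sem[1]:.3f}")
    print(f"  planned paired t: {t}")

    null = cohort_summary(run_cohort(
        12, SubjectConfig(decouple_fidelity=True), seed=SEED + 1))
    tn = null["similarity_contrast"]
    print("decoupled-fidelity control cohort (no accuracy-pattern coupling):")
    print(f"  z_correct - z_incorrect = "
          f"{(null['z_correct'] - null['z_incorrect']).mean():.3f} ({tn})")
    print("  (the residual positive offset is the trial-count attenuation "
          "artifact discussed in docs/methods.md)")


if __name__ == "__main__":
    main()
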