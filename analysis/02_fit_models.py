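#!/usr/bin/env python
"""Fit the candidate learning models and compare them by BIC.

Reads the trial table written by 01_simulate_cohort.py, fits the null
model (M0), the shared-parameter model (M1) and the condition-separate
model (M2) to every subject and block by maximum likelihood, sums BIC
per model within each block, and applies the exclusion rules (majority
missing responses; no evidence of self-regarding learning at baseline).
"""

import argparse
from pathlib import Path

import pandas as pd

from prlearn.fitting import apply_exclusions, compare_models, fit_dataset
from prlearn.io import read_trials, write_fits

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

datasets = read_trials(args.out / "trials.csv")
fits = []
for ds in datasets:
    fits.extend(fit_dataset(ds))
write_fits(fits, args.out / "fits.csv")

rows = []
for block in (1, 2, 3):
    comp = compare_models(fits, block)
    rows.append({"block": block, **{f"bic_{m}": v for m, v in comp.summed_bic.items()},
                 **{f"dbic_{k}": v for k, v in comp.delta_bic.items()}})
    winner = min(comp.summed_bic, key=comp.summed_bic.get)
    print(f"block {block}: winner {winner}; summed BIC "
          + ", ".join(f"{m}={v:.1f}" for m, v in comp.summed_bic.items()))
pd.DataFrame(rows).to_csv(args.out / "model_comparison.csv", index=False)

report = apply_exclusions(datasets, fits)
pd.DataFrame(
    [{"subject": s, "reason": "; ".join(r)} for s, r in report.excluded.items()]
).to_csv(args.out / "exclusions.csv", index=False)
print(f"{len(report.included)} subjects retained, "
      f"{len(report.excluded)} excluded")
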