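#!/usr/bin/env python
"""Evaluate scale-score mapping families on incomplete questionnaires.

Families that predict from scale scores (linear on scales, response
mapping, beta regression, separate equations) still apply when a
questionnaire has missing items, as long as each required scale clears
the half-completion rule.  Models fitted on the complete cohort are
applied to the incomplete cohort's eligible rows; no imputation is
performed.  Writes results/table_performance_incomplete.csv.
"""

from pathlib import Path

import pandas as pd

from qolmap.pipeline import read_cohort_csv
from qolmap.serialize import load_model
from qolmap.validation import evaluate_incomplete

RESULTS = Path(__file__).resolve().parent.parent / "results"
FAMILIES = ["linear_scales", "response_mapping", "beta", "separate_equations"]
METRICS = ["mean", "sd", "min", "max", "rmse", "mae", "spearman", "t_pvalue"]


def main() -> None:
    incomplete = read_cohort_csv(RESULTS / "cohort_incomplete.csv")
    models = {f: load_model(RESULTS / "models" / f"{f}.json") for f in FAMILIES}
    results = evaluate_incomplete(incomplete, models, "NL")
    cols = {}
    for family, entry in results.items():
        cols[family] = {**entry["metrics"].to_dict(), "n_eligible": entry["n_eligible"]}
        print(f"{family:20s} eligible {entry['n_eligible']:4d}  "
              f"RMSE {entry['metrics'].rmse:.3f}  MAE {entry['metrics'].mae:.3f}")
    table = pd.DataFrame({name: {m: vals.get(m) for m in METRICS + ["n_eligible"]}
                          for name, vals in cols.items()})
    table.to_csv(RESULTS / "table_performance_incomplete.csv",
                 float_format="%.3f", index_label="metric")


if __name__ == "__main__":
    main()
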