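#!/usr/bin/env python
"""Score both instruments on the simulated cohort.

Derives the 15 QLQ-C30 scale scores (half-completion rule) and the
Dutch-tariff EQ-5D-3L utilities, writing results/scored.csv.  Prints the
observed-utility summary that later stages compare mapped utilities to.
"""

from pathlib import Path

from qolmap.instruments import load_value_set, score_qlqc30
from qolmap.pipeline import read_cohort_csv, write_cohort_csv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort.csv")
    scores = score_qlqc30(cohort)
    for c in scores.columns:
        cohort[c] = scores[c]
    vs = load_value_set("NL")
    cohort["utility"] = vs.utility_frame(cohort)
    write_cohort_csv(cohort, RESULTS / "scored.csv")

    u = cohort["utility"]
    print(f"scored {len(cohort)} questionnaires with the {vs.name} tariff")
    print(f"observed utility: mean {u.mean():.3f}, sd {u.std(ddof=1):.3f}, "
          f"min {u.min():.3f}, max {u.max():.3f}")


if __name__ == "__main__":
    main()
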