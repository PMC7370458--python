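#!/usr/bin/env python
"""Fit all six mapping-model families on the complete scored cohort.

Each family runs its full estimation recipe (backward selection at
p = 0.05 plus non-logical-coefficient pruning where applicable) and is
saved as a coefficient JSON under results/models/.  The selection audit
trail — which terms were dropped, and whether for significance or for an
incongruous sign — is written alongside.
"""

import json
from pathlib import Path

from qolmap.pipeline import read_cohort_csv
from qolmap.serialize import model_to_dict
from qolmap.validation import MODEL_FAMILIES, fit_family

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = read_cohort_csv(RESULTS / "scored.csv")
    outdir = RESULTS / "models"
    outdir.mkdir(exist_ok=True)
    audit = {}
    for family in MODEL_FAMILIES:
        fitted = fit_family(family, data, "NL")
        model = getattr(fitted, "model", fitted)
        (outdir / f"{family}.json").write_text(
            json.dumps(model_to_dict(model), indent=2, sort_keys=True) + "\n")
        history = getattr(fitted, "history", [])
        audit[family] = history
        dropped_p = sum(1 for h in history if h["reason"] == "p_value")
        dropped_sign = sum(1 for h in history if h["reason"] == "sign")
        print(f"{family:20s} dropped {dropped_p} non-significant and "
              f"{dropped_sign} non-logical terms")
        for h in history:
            if h["reason"] == "sign":
                print(f"    non-logical: {h.get('submodel', '')} {h['term']} "
                      f"(coef {h['coef']:+.4g})")
    (outdir / "selection_audit.json").write_text(
        json.dumps(audit, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
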