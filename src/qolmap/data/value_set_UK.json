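{
  "name": "UK",
  "provenance": "UK EQ-5D-3L MVH A1 time trade-off tariff (Dolan P, Med Care 1997). Additive model: 1 minus a 0.081 any-dysfunction constant, minus per-domain level decrements, minus a 0.269 N3 term when any domain is at level 3. State 3-3-3-3-3 scores -0.594. Packaged as the conventional UK 3L tariff; swap the file to use another UK variant.",
  "constant": 1.0,
  "decrements": {
    "mobility": {"1": 0.0, "2": 0.069, "3": 0.314},
    "self_care": {"1": 0.0, "2": 0.104, "3": 0.214},
    "usual_activities": {"1": 0.0, "2": 0.036, "3": 0.094},
    "pain_discomfort": {"1": 0.0, "2": 0.123, "3": 0.386},
    "anxiety_depression": {"1": 0.0, "2": 0.071, "3": 0.236}
  },
  "extras": [
    {"predicate": "any_gt_1", "value": 0.081},
    {"predicate": "any_eq_3", "value": 0.269}
  ]
}
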