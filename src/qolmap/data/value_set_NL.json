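{
  "name": "NL",
  "provenance": "Dutch EQ-5D-3L time trade-off tariff (Lamers LM et al., Ned Tijdschr Geneeskd 2005 / Health Econ 2006). Additive MVH-style model: 1 minus a 0.071 any-dysfunction constant, minus per-domain level decrements, minus a 0.234 N3 term when any domain is at level 3. State 3-3-3-3-3 scores -0.329.",
  "constant": 1.0,
  "decrements": {
    "mobility": {"1": 0.0, "2": 0.036, "3": 0.161},
    "self_care": {"1": 0.0, "2": 0.082, "3": 0.152},
    "usual_activities": {"1": 0.0, "2": 0.032, "3": 0.057},
    "pain_discomfort": {"1": 0.0, "2": 0.086, "3": 0.329},
    "anxiety_depression": {"1": 0.0, "2": 0.124, "3": 0.325}
  },
  "extras": [
    {"predicate": "any_gt_1", "value": 0.071},
    {"predicate": "any_eq_3", "value": 0.234}
  ]
}
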