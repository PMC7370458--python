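{
  "name": "mcrc_scale_scores",
  "family": "linear_scales",
  "tariff": "NL",
  "description": "Reference linear mapping from QLQ-C30 functional/symptom scale scores to Dutch-tariff EQ-5D-3L utilities, estimated on a metastatic colorectal cancer cohort (random-intercept panel model after backward selection and sign pruning).",
  "inputs": ["physical", "role", "emotional", "cognitive", "social", "pain", "insomnia"],
  "intercept": 0.2993,
  "coefficients": {
    "physical": 0.0021,
    "role": 0.0011,
    "emotional": 0.0025,
    "cognitive": 0.0005,
    "social": 0.0006,
    "pain": -0.0023,
    "insomnia": -0.0005
  }
}
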