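{
  "version": "1",
  "description": "Decision rules grading diabetic retinopathy into five severity levels from the nine lesion features, with leaf confidences in percent.",
  "rules": [
    {
      "rule_id": "no_dr",
      "severity": 0,
      "label": "No DR",
      "confidence": 95.125,
      "predicates": [
        {"feature": "R_SE", "comparator": "le", "threshold": 0.18},
        {"feature": "R_HE", "comparator": "le", "threshold": 0.052},
        {"feature": "N_SE", "comparator": "eq", "threshold": 0}
      ]
    },
    {
      "rule_id": "mild",
      "severity": 1,
      "label": "Mild DR",
      "confidence": 99.396,
      "predicates": [
        {"feature": "R_SE", "comparator": "le", "threshold": 0.18},
        {"feature": "R_HE", "comparator": "le", "threshold": 0.052},
        {"feature": "N_SE", "comparator": "in_int_range", "threshold": [1, 15]},
        {"feature": "R_SE", "comparator": "le", "threshold": 0.111}
      ]
    },
    {
      "rule_id": "moderate_se",
      "severity": 2,
      "label": "Moderate DR",
      "confidence": 95.238,
      "predicates": [
        {"feature": "R_SE", "comparator": "le", "threshold": 0.18},
        {"feature": "R_HE", "comparator": "le", "threshold": 0.052},
        {"feature": "N_SE", "comparator": "in_int_range", "threshold": [1, 15]},
        {"feature": "R_SE", "comparator": "gt", "threshold": 0.111}
      ]
    },
    {
      "rule_id": "moderate_he",
      "severity": 2,
      "label": "Moderate DR",
      "confidence": 99.7,
      "predicates": [
        {"feature": "R_SE", "comparator": "le", "threshold": 0.18},
        {"feature": "R_HE", "comparator": "gt", "threshold": 0.052},
        {"feature": "R_HE", "comparator": "le", "threshold": 0.171}
      ]
    },
    {
      "rule_id": "severe_he",
      "severity": 3,
      "label": "Severe DR",
      "confidence": 58.824,
      "predicates": [
        {"feature": "R_SE", "comparator": "le", "threshold": 0.18},
        {"feature": "R_HE", "comparator": "ge", "threshold": 0.052},
        {"feature": "R_HE", "comparator": "gt", "threshold": 0.171}
      ]
    },
    {
      "rule_id": "severe_se",
      "severity": 3,
      "label": "Severe DR",
      "confidence": 92.381,
      "predicates": [
        {"feature": "R_SE", "comparator": "gt", "threshold": 0.18},
        {"feature": "N_NV", "comparator": "eq", "threshold": 0},
        {"feature": "R_SE", "comparator": "le", "threshold": 0.342},
        {"feature": "R_HE", "comparator": "le", "threshold": 0.343}
      ]
    },
    {
      "rule_id": "proliferate_nv",
      "severity": 4,
      "label": "Proliferate DR",
      "confidence": 100.0,
      "predicates": [
        {"feature": "R_SE", "comparator": "gt", "threshold": 0.18},
        {"feature": "N_NV", "comparator": "in_int_range", "threshold": [1, 3]}
      ]
    },
    {
      "rule_id": "proliferate_se",
      "severity": 4,
      "label": "Proliferate DR",
      "confidence": 100.0,
      "predicates": [
        {"feature": "R_SE", "comparator": "gt", "threshold": 0.18},
        {"feature": "N_NV", "comparator": "eq", "threshold": 0},
        {"feature": "R_SE", "comparator": "gt", "threshold": 0.342}
      ]
    },
    {
      "rule_id": "proliferate_he",
      "severity": 4,
      "label": "Proliferate DR",
      "confidence": 100.0,
      "predicates": [
        {"feature": "R_SE", "comparator": "gt", "threshold": 0.18},
        {"feature": "N_NV", "comparator": "eq", "threshold": 0},
        {"feature": "R_SE", "comparator": "le", "threshold": 0.342},
        {"feature": "R_HE", "comparator": "gt", "threshold": 0.343}
      ]
    }
  ]
}
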