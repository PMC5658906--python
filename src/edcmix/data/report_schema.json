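{
  "class_summary": [
    "parameter", "mean", "sd",
    "ci50_lower", "ci50_upper", "excl_zero_50",
    "ci95_lower", "ci95_upper", "excl_zero_95",
    "scale"
  ],
  "chemical_summary": [
    "parameter", "chem_class", "mean", "sd",
    "ci50_lower", "ci50_upper", "excl_zero_50",
    "ci95_lower", "ci95_upper", "excl_zero_95",
    "scale"
  ],
  "recovery_metrics": [
    "parameter", "class", "truth", "bias", "rmse",
    "coverage95", "coverage50", "median_estimate"
  ]
}
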