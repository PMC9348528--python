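{
  "description": "Measured release parameters of the optimized nanofiber formulation, the ANN estimates of the same quantities, the published relative estimation errors, and the GA-optimal chromosome. The pH 4.4 loading-efficiency figure is recorded as parsed from an ambiguously grouped source table and is reference-only. The published RTRmax error (10.65%) is not reproducible from the printed measured/estimated pair (|86.22-78.22|/78.22 = 10.23%) and is likewise reference-only.",
  "ph_7_4": {
    "rtrmax_percent": 78.22, "trmax_h": 144, "br_percent": 34.41, "le_percent": 81.48,
    "peppas": {"k": 0.42, "n": 0.13, "r2": 0.99},
    "weibull": {"a": 20.6, "b": 0.23, "r2": 0.99}
  },
  "ph_4_4": {
    "rtrmax_percent": 74.8, "trmax_h": 72, "br_percent": 35.7, "le_percent": 40.45,
    "peppas": {"k": 0.45, "n": 0.12, "r2": 0.97},
    "weibull": {"a": 16.8, "b": 0.20, "r2": 0.97}
  },
  "ann_estimate": {
    "rtrmax_percent": 86.22, "trmax_h": 141, "br_percent": 36.07, "le_percent": 86.22
  },
  "ann_error_percent": {
    "rtrmax": 10.65, "trmax": 2.08, "br": 4.82, "le": 5.82
  },
  "ga_optimum": {
    "feeding_ratio": 2, "cs_percent": 22, "np_percent": 5.9, "drug_percent": 4.6,
    "fitness": 0.2065
  }
}
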