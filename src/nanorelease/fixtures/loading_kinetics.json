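{
  "description": "Per-run drug loading efficiency (mean +/- SD over n=3 replicates) and published Korsmeyer-Peppas / Weibull coefficients for the 18 design runs. The Weibull (a, b) values are recorded as printed; their normalization is not reconstructible from hour-scale release fractions, so they are reference data only.",
  "runs": [
    {"code": "C1",  "drug_theoretical_percent": 3, "le_mean": 61.92, "le_sd": 1.80, "peppas": {"k": 0.34, "n": 0.16, "r2": 0.97}, "weibull": {"a": 46.7, "b": 0.24, "r2": 0.96}},
    {"code": "C2",  "drug_theoretical_percent": 1, "le_mean": 64.45, "le_sd": 1.37, "peppas": {"k": 0.36, "n": 0.14, "r2": 0.98}, "weibull": {"a": 53.4, "b": 0.22, "r2": 0.96}},
    {"code": "C3",  "drug_theoretical_percent": 5, "le_mean": 65.91, "le_sd": 1.42, "peppas": {"k": 0.37, "n": 0.14, "r2": 0.97}, "weibull": {"a": 38.9, "b": 0.23, "r2": 0.96}},
    {"code": "C4",  "drug_theoretical_percent": 5, "le_mean": 64.99, "le_sd": 1.19, "peppas": {"k": 0.39, "n": 0.13, "r2": 0.98}, "weibull": {"a": 35.7, "b": 0.22, "r2": 0.97}},
    {"code": "C5",  "drug_theoretical_percent": 3, "le_mean": 67.40, "le_sd": 1.08, "peppas": {"k": 0.39, "n": 0.13, "r2": 0.99}, "weibull": {"a": 35.9, "b": 0.21, "r2": 0.98}},
    {"code": "C6",  "drug_theoretical_percent": 1, "le_mean": 72.19, "le_sd": 1.71, "peppas": {"k": 0.39, "n": 0.14, "r2": 0.98}, "weibull": {"a": 30.5, "b": 0.23, "r2": 0.98}},
    {"code": "C7",  "drug_theoretical_percent": 1, "le_mean": 78.65, "le_sd": 1.27, "peppas": {"k": 0.39, "n": 0.14, "r2": 0.99}, "weibull": {"a": 25.0, "b": 0.24, "r2": 0.99}},
    {"code": "C8",  "drug_theoretical_percent": 5, "le_mean": 81.43, "le_sd": 1.60, "peppas": {"k": 0.40, "n": 0.15, "r2": 0.99}, "weibull": {"a": 18.9, "b": 0.26, "r2": 0.98}},
    {"code": "C9",  "drug_theoretical_percent": 3, "le_mean": 83.56, "le_sd": 1.33, "peppas": {"k": 0.42, "n": 0.14, "r2": 0.98}, "weibull": {"a": 15.2, "b": 0.26, "r2": 0.98}},
    {"code": "C10", "drug_theoretical_percent": 1, "le_mean": 65.29, "le_sd": 1.22, "peppas": {"k": 0.36, "n": 0.15, "r2": 0.98}, "weibull": {"a": 37.3, "b": 0.24, "r2": 0.99}},
    {"code": "C11", "drug_theoretical_percent": 5, "le_mean": 66.47, "le_sd": 0.94, "peppas": {"k": 0.38, "n": 0.14, "r2": 0.99}, "weibull": {"a": 31.6, "b": 0.23, "r2": 0.99}},
    {"code": "C12", "drug_theoretical_percent": 3, "le_mean": 69.36, "le_sd": 1.25, "peppas": {"k": 0.38, "n": 0.14, "r2": 0.97}, "weibull": {"a": 34.8, "b": 0.22, "r2": 0.97}},
    {"code": "C13", "drug_theoretical_percent": 5, "le_mean": 68.76, "le_sd": 1.39, "peppas": {"k": 0.39, "n": 0.12, "r2": 0.94}, "weibull": {"a": 39.8, "b": 0.21, "r2": 0.91}},
    {"code": "C14", "drug_theoretical_percent": 3, "le_mean": 73.26, "le_sd": 1.11, "peppas": {"k": 0.40, "n": 0.13, "r2": 0.98}, "weibull": {"a": 32.0, "b": 0.22, "r2": 0.97}},
    {"code": "C15", "drug_theoretical_percent": 1, "le_mean": 77.21, "le_sd": 2.16, "peppas": {"k": 0.41, "n": 0.13, "r2": 0.97}, "weibull": {"a": 24.4, "b": 0.22, "r2": 0.96}},
    {"code": "C16", "drug_theoretical_percent": 3, "le_mean": 80.14, "le_sd": 1.94, "peppas": {"k": 0.43, "n": 0.12, "r2": 0.98}, "weibull": {"a": 18.9, "b": 0.22, "r2": 0.97}},
    {"code": "C17", "drug_theoretical_percent": 1, "le_mean": 83.49, "le_sd": 2.08, "peppas": {"k": 0.43, "n": 0.13, "r2": 0.98}, "weibull": {"a": 14.6, "b": 0.25, "r2": 0.98}},
    {"code": "C18", "drug_theoretical_percent": 5, "le_mean": 86.14, "le_sd": 1.05, "peppas": {"k": 0.44, "n": 0.14, "r2": 0.98}, "weibull": {"a": 12.7, "b": 0.26, "r2": 0.97}}
  ]
}
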