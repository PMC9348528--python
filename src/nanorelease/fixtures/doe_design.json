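{
  "description": "L18-style Taguchi design of the core-shell nanofiber release study. Factors: sheath:core feeding ratio, sheath polymer ratio (PCL:CS volume parts), Fe3O4 %, 5FU %, AMF frequency (kHz; 0 = no field).",
  "runs": [
    {"code": "C1",  "feeding_ratio": 1.25, "pcl_parts": 2, "cs_parts": 1, "np_percent": 1, "drug_percent": 3, "amf_frequency_khz": 0},
    {"code": "C2",  "feeding_ratio": 1.25, "pcl_parts": 2, "cs_parts": 1, "np_percent": 3, "drug_percent": 1, "amf_frequency_khz": 400},
    {"code": "C3",  "feeding_ratio": 1.25, "pcl_parts": 2, "cs_parts": 1, "np_percent": 7, "drug_percent": 5, "amf_frequency_khz": 300},
    {"code": "C4",  "feeding_ratio": 1.25, "pcl_parts": 1, "cs_parts": 1, "np_percent": 1, "drug_percent": 5, "amf_frequency_khz": 400},
    {"code": "C5",  "feeding_ratio": 1.25, "pcl_parts": 1, "cs_parts": 1, "np_percent": 3, "drug_percent": 3, "amf_frequency_khz": 300},
    {"code": "C6",  "feeding_ratio": 1.25, "pcl_parts": 1, "cs_parts": 1, "np_percent": 7, "drug_percent": 1, "amf_frequency_khz": 0},
    {"code": "C7",  "feeding_ratio": 1.25, "pcl_parts": 1, "cs_parts": 2, "np_percent": 1, "drug_percent": 1, "amf_frequency_khz": 300},
    {"code": "C8",  "feeding_ratio": 1.25, "pcl_parts": 1, "cs_parts": 2, "np_percent": 3, "drug_percent": 5, "amf_frequency_khz": 0},
    {"code": "C9",  "feeding_ratio": 1.25, "pcl_parts": 1, "cs_parts": 2, "np_percent": 7, "drug_percent": 3, "amf_frequency_khz": 400},
    {"code": "C10", "feeding_ratio": 2,    "pcl_parts": 2, "cs_parts": 1, "np_percent": 1, "drug_percent": 1, "amf_frequency_khz": 400},
    {"code": "C11", "feeding_ratio": 2,    "pcl_parts": 2, "cs_parts": 1, "np_percent": 3, "drug_percent": 5, "amf_frequency_khz": 300},
    {"code": "C12", "feeding_ratio": 2,    "pcl_parts": 2, "cs_parts": 1, "np_percent": 7, "drug_percent": 3, "amf_frequency_khz": 0},
    {"code": "C13", "feeding_ratio": 2,    "pcl_parts": 1, "cs_parts": 1, "np_percent": 1, "drug_percent": 5, "amf_frequency_khz": 0},
    {"code": "C14", "feeding_ratio": 2,    "pcl_parts": 1, "cs_parts": 1, "np_percent": 3, "drug_percent": 3, "amf_frequency_khz": 400},
    {"code": "C15", "feeding_ratio": 2,    "pcl_parts": 1, "cs_parts": 1, "np_percent": 7, "drug_percent": 1, "amf_frequency_khz": 300},
    {"code": "C16", "feeding_ratio": 2,    "pcl_parts": 1, "cs_parts": 2, "np_percent": 1, "drug_percent": 3, "amf_frequency_khz": 300},
    {"code": "C17", "feeding_ratio": 2,    "pcl_parts": 1, "cs_parts": 2, "np_percent": 3, "drug_percent": 1, "amf_frequency_khz": 0},
    {"code": "C18", "feeding_ratio": 2,    "pcl_parts": 1, "cs_parts": 2, "np_percent": 7, "drug_percent": 5, "amf_frequency_khz": 400}
  ]
}
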