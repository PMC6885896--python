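{
  "_comment": "Illustrative synthetic code lists for testing and demonstration. NOT clinically validated; supply real NDC/HCPCS/ICD lists for analyses of real claims data.",
  "drug_catalog": [
    {"code": "J9310", "agent": "rituximab", "route": "infusion"},
    {"code": "J9070", "agent": "cyclophosphamide", "route": "infusion"},
    {"code": "J9000", "agent": "doxorubicin", "route": "infusion"},
    {"code": "J9370", "agent": "vincristine", "route": "infusion"},
    {"code": "J9033", "agent": "bendamustine", "route": "infusion"},
    {"code": "J9041", "agent": "bortezomib", "route": "infusion"},
    {"code": "J9100", "agent": "cytarabine", "route": "infusion"},
    {"code": "57962014012", "agent": "ibrutinib", "route": "oral"},
    {"code": "00310051260", "agent": "acalabrutinib", "route": "oral"},
    {"code": "59572040500", "agent": "lenalidomide", "route": "oral"},
    {"code": "00054472925", "agent": "prednisone", "route": "oral", "is_mcl_treatment": false, "is_corticosteroid": true},
    {"code": "00054418425", "agent": "dexamethasone", "route": "oral", "is_mcl_treatment": false, "is_corticosteroid": true}
  ],
  "mcl_dx_prefixes": ["200", "C83.1"],
  "ae_codes": {
    "anemia": {"prefixes": ["D64", "285.9"]},
    "arthralgia_myalgia": {"prefixes": ["M25.5", "M79.1", "719.4", "729.1"]},
    "atrial_fibrillation": {"prefixes": ["I48", "427.31"]},
    "cerebrovascular": {"prefixes": ["I60", "I61", "I63", "I64", "430", "431", "433", "434", "436"]},
    "diarrhea": {"prefixes": ["R19.7", "K52", "787.91"]},
    "hemorrhage_bleeding": {"prefixes": ["R58", "K92.2", "459.0"]},
    "hepatotoxicity": {"prefixes": ["K71", "573.3"]},
    "hypertension": {"prefixes": ["I10", "401"]},
    "infection": {"prefixes": ["A4", "B99", "038.9", "J18", "486"]},
    "leukopenia": {"prefixes": ["D72.8", "288.5"]},
    "myocardial_infarction": {"prefixes": ["I21", "410"]},
    "neutropenia": {"prefixes": ["D70", "288.0"]},
    "renal_failure": {"prefixes": ["N17", "N18", "N19", "584", "585", "586"]},
    "secondary_malignancy": {
      "prefixes": ["C77", "C78", "C79", "C80", "196", "197", "198", "199"],
      "exclude_prefixes": ["C96", "202"],
      "rule": "two_claims_7d"
    },
    "thrombocytopenia": {"prefixes": ["D69.6", "287.5"]}
  },
  "comorbidity_codes": {
    "infection": ["A4", "B99", "038.9", "J18", "486"],
    "hypertension": ["I10", "401"],
    "anemia": ["D64", "285.9"],
    "fatigue_asthenia": ["R53", "780.7"],
    "hemorrhage_bleeding": ["R58", "K92.2", "459.0"],
    "thrombocytopenia": ["D69.6", "287.5"],
    "edema": ["R60", "782.3"],
    "nausea_vomiting": ["R11", "787.0"],
    "neutropenia": ["D70", "288.0"],
    "renal_failure": ["N17", "N18", "N19", "584", "585", "586"],
    "diarrhea": ["R19.7", "K52", "787.91"],
    "pneumonia": ["J18", "486"],
    "arthralgia_myalgia": ["M25.5", "M79.1", "719.4", "729.1"],
    "leukopenia": ["D72.8", "288.5"],
    "atrial_fibrillation": ["I48", "427.31"],
    "hepatotoxicity": ["K71", "573.3"],
    "diabetes": ["E10", "E11", "250"],
    "heart_failure": ["I50", "428"],
    "obesity": ["E66", "278.0"],
    "sleep_apnea": ["G47.33", "327.23"],
    "chronic_pulmonary": ["J44", "496"]
  },
  "cci": {
    "myocardial_infarction": {"weight": 1, "prefixes": ["I21", "I22", "410", "412"]},
    "congestive_heart_failure": {"weight": 1, "prefixes": ["I50", "428"]},
    "peripheral_vascular": {"weight": 1, "prefixes": ["I70", "I71", "440", "441"]},
    "cerebrovascular": {"weight": 1, "prefixes": ["I60", "I61", "I63", "I64", "430", "433", "434", "436"]},
    "dementia": {"weight": 1, "prefixes": ["F00", "F01", "F02", "F03", "290"]},
    "chronic_pulmonary": {"weight": 1, "prefixes": ["J40", "J41", "J42", "J43", "J44", "J45", "490", "491", "492", "493", "496"]},
    "rheumatic": {"weight": 1, "prefixes": ["M05", "M06", "M32", "M33", "M34", "710.0", "714"]},
    "peptic_ulcer": {"weight": 1, "prefixes": ["K25", "K26", "K27", "K28", "531", "532", "533", "534"]},
    "mild_liver": {"weight": 1, "prefixes": ["B18", "K70", "K73", "K74", "571"]},
    "diabetes": {"weight": 1, "prefixes": ["E10", "E11", "250"]},
    "diabetes_complications": {"weight": 2, "prefixes": ["E10.2", "E11.2", "250.4", "250.5"]},
    "hemiplegia": {"weight": 2, "prefixes": ["G81", "G82", "342", "344"]},
    "renal_disease": {"weight": 2, "prefixes": ["N18", "N19", "585", "586"]},
    "malignancy": {"weight": 2, "prefixes": ["C83", "C18", "C34", "C50", "C61", "200", "153", "162", "174", "185"]},
    "moderate_severe_liver": {"weight": 3, "prefixes": ["I85", "K72", "K76.6", "572.2", "572.3"]},
    "metastatic_solid_tumor": {"weight": 6, "prefixes": ["C77", "C78", "C79", "C80", "196", "197", "198", "199"]},
    "aids": {"weight": 6, "prefixes": ["B20", "042"]}
  },
  "af_risk": {
    "factors": {
      "hypertension": {"points": 1, "prefixes": ["I10", "401"]},
      "diabetes": {"points": 1, "prefixes": ["E10", "E11", "250"]},
      "heart_failure": {"points": 2, "prefixes": ["I50", "428"]},
      "obesity": {"points": 1, "prefixes": ["E66", "278.0"]},
      "sleep_apnea": {"points": 1, "prefixes": ["G47.33", "327.23"]}
    },
    "threshold": 2
  },
  "cpi": {
    "2012": 0.926,
    "2013": 0.939,
    "2014": 0.955,
    "2015": 0.956,
    "2016": 0.968,
    "2017": 1.0,
    "2018": 1.024
  }
}
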