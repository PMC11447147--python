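{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "dyadscan cohort table",
  "type": "object",
  "missing_token": "NA",
  "required": [
    "subject_id",
    "status",
    "sex",
    "age_at_assessment",
    "paternal_history",
    "maternal_history",
    "father_birthplace",
    "mother_birthplace"
  ],
  "properties": {
    "subject_id": {
      "type": "string",
      "description": "unique opaque id"
    },
    "status": {
      "enum": [
        "case",
        "control"
      ]
    },
    "sex": {
      "enum": [
        "male",
        "female"
      ]
    },
    "age_at_assessment": {
      "type": "number",
      "unit": "years"
    },
    "age_of_onset": {
      "type": "number",
      "unit": "years",
      "nullable": true
    },
    "education": {
      "type": "number",
      "unit": "years",
      "nullable": true
    },
    "year_of_birth": {
      "type": "integer",
      "nullable": true
    },
    "paternal_history": {
      "enum": [
        "yes",
        "no",
        "unknown"
      ]
    },
    "maternal_history": {
      "enum": [
        "yes",
        "no",
        "unknown"
      ]
    },
    "father_birthplace": {
      "type": "string",
      "nullable": true
    },
    "mother_birthplace": {
      "type": "string",
      "nullable": true
    },
    "n_siblings": {
      "type": "integer",
      "nullable": true
    },
    "siblings_with_dementia": {
      "type": "integer",
      "nullable": true
    },
    "apoe": {
      "type": "string",
      "pattern": "^e[234]/e[234]$",
      "nullable": true
    },
    "csf_abeta42": {
      "type": "number",
      "unit": "pg/mL",
      "nullable": true
    },
    "csf_ttau": {
      "type": "number",
      "unit": "pg/mL",
      "nullable": true
    },
    "csf_ptau": {
      "type": "number",
      "unit": "pg/mL",
      "nullable": true
    },
    "age_at_lp": {
      "type": "number",
      "unit": "years",
      "nullable": true
    }
  }
}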