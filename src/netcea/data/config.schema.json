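{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "netcea model configuration",
  "description": "YAML/JSON config dialect accepted by netcea.load_config. Every key is optional; omitted keys keep their built-in base-case defaults. Unknown keys are rejected. Probabilities and utilities must lie in [0, 1]; costs must be non-negative.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "prevalence": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1, "default": 0.05},
    "start_age": {"type": "integer", "default": 30},
    "horizon_age": {"type": "integer", "default": 100},
    "discount_rate": {"type": "number", "minimum": 0, "default": 0.03},
    "wtp": {"type": "number", "minimum": 0, "default": 100000},
    "cycle_length": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
    "life_table_ref": {"type": "string", "default": "bundled", "description": "'bundled' or a path to a two-column (age, qx) CSV"},
    "psa_iterations": {"type": "integer", "minimum": 1, "default": 30000},
    "seed": {"type": "integer", "default": 20210218},
    "charge_biopsy_to_test_positives": {"type": "boolean", "default": true},
    "psa_ess": {"type": "number", "exclusiveMinimum": 0, "default": 100.0},
    "psa_cv": {"type": "number", "exclusiveMinimum": 0, "default": 0.2},
    "psa_spread_overrides": {
      "type": "object",
      "additionalProperties": {"type": "number", "exclusiveMinimum": 0},
      "description": "per-parameter spread (effective sample size for beta, coefficient of variation for gamma), keyed by dotted parameter name"
    },
    "dsa_fraction": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.2},
    "strategies": {
      "type": "array",
      "description": "partial entries merge into the default strategy of the same name; new names need all fields",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "imaging_cost": {"type": "number", "minimum": 0},
          "sensitivity": {"type": "number", "minimum": 0, "maximum": 1},
          "specificity": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "costs": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "timely_treatment": {"type": "number", "minimum": 0, "default": 85068.0},
        "delayed_treatment": {"type": "number", "minimum": 0, "default": 127602.0},
        "unnecessary_biopsy": {"type": "number", "minimum": 0, "default": 1375.0},
        "true_negative_acute": {"type": "number", "minimum": 0, "default": 0.0},
        "biopsy": {"type": "number", "minimum": 0, "default": 1375.0},
        "yearly_no_burden": {"type": "number", "minimum": 0, "default": 0.0},
        "yearly_treated_non_relevant": {"type": "number", "minimum": 0, "default": 2107.0},
        "yearly_clinically_relevant": {"type": "number", "minimum": 0, "default": 61375.0}
      }
    },
    "utilities": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "no_burden": {"type": "number", "minimum": 0, "maximum": 1, "default": 1.0},
        "no_clinically_relevant_burden": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.779},
        "clinically_relevant_treated": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.768},
        "progression_untreated": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.612},
        "without_treatment_alt": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.690},
        "death": {"type": "number", "const": 0.0}
      }
    },
    "transitions": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "p_death_timely": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.04},
        "p_death_delayed": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.045},
        "p_death_untreated": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.1212},
        "p_death_competing": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.025},
        "p_progression": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.088},
        "p_untreated_to_treated": {"type": "number", "minimum": 0, "maximum": 1, "default": 1.0},
        "relative_risk_other_death": {"type": "number", "minimum": 0, "default": 1.0}
      }
    }
  }
}
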